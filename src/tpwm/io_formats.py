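"""Readers and writers: FASTA, TRANSFAC/JASPAR matrices, IUPAC consensus
initialization, and the TPWM JSON schema.

Every reader rejects malformed input with an error naming the offending
location rather than repairing it silently.
"""

from __future__ import annotations

import json

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model_core import ALPHABET, PWM, TPWM, TPWMNode

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_transfac",
    "write_transfac",
    "read_matrix",
    "write_pwm_tsv",
    "read_pwm_tsv",
    "consensus_to_pwm",
    "tpwm_to_json",
    "tpwm_from_json",
    "save_tpwm",
    "load_tpwm",
    "IUPAC_CODES",
]

TPWM_JSON_VERSION = 1

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


# --------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercased sequence) pairs via Bio.SeqIO."""
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


# --------------------------------------------------------------------------
# count matrices


def read_transfac(path, pseudocount: float = 0.0) -> PWM:
    """Parse a TRANSFAC matrix block (also accepts the JASPAR PFM dialect).

    TRANSFAC: a ``PO``/``P0`` header whose columns name the nucleotides,
    followed by numbered rows of 4 counts (XX/CC/ID/BF/NA metadata and ``//``
    terminators are ignored).  JASPAR: four lines ``A [ 1 2 ... ]`` (brackets
    optional), one per nucleotide, optionally preceded by a ``>`` header.
    """
    with open(path) as fh:
        lines = fh.readlines()
    rows: list[list[float]] = []
    order = None
    jaspar: dict[str, list[float]] = {}
    for ln, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("XX", "CC", "ID", "BF", "NA", "//", ";", ">")):
            continue
        parts = line.replace("[", " ").replace("]", " ").split()
        head = parts[0].upper()
        if head in ("PO", "P0"):
            order = [p.upper() for p in parts[1:5]]
            if sorted(order) != list(ALPHABET):
                raise ValueError(
                    f"{path}:{ln}: header must name A, C, G and T, got {parts[1:]}"
                )
            continue
        if head in "ACGT" and len(head) == 1:
            if head in jaspar:
                raise ValueError(f"{path}:{ln}: duplicate row for nucleotide {head}")
            try:
                jaspar[head] = [float(x) for x in parts[1:]]
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-numeric count") from None
            continue
        try:
            int(head)
        except ValueError:
            raise ValueError(
                f"{path}:{ln}: unrecognized line {line!r}"
            ) from None
        vals = parts[1:5]
        if len(vals) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 counts, found {len(vals)}")
        try:
            rows.append([float(x) for x in vals])
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-numeric count") from None

    if jaspar:
        if rows:
            raise ValueError(f"{path}: mixes TRANSFAC rows and JASPAR rows")
        if set(jaspar) != set(ALPHABET):
            raise ValueError(
                f"{path}: JASPAR block must have one row per nucleotide, "
                f"got {sorted(jaspar)}"
            )
        widths = {len(v) for v in jaspar.values()}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged JASPAR rows, lengths {sorted(widths)}")
        counts = np.array([jaspar[a] for a in ALPHABET]).T
    else:
        if not rows:
            raise ValueError(f"{path}: no matrix rows found")
        counts = np.asarray(rows)
        if order is not None:
            perm = [order.index(a) for a in ALPHABET]
            counts = counts[:, perm]
    if (counts < 0).any():
        raise ValueError(f"{path}: negative count in matrix")
    return _pwm_from_counts(counts, pseudocount)


def _pwm_from_counts(counts: np.ndarray, pseudocount: float) -> PWM:
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("matrix column with zero total count")
    probs = (counts + pseudocount) / (totals + 4.0 * pseudocount)
    int_counts = None
    if np.allclose(counts, np.round(counts)):
        int_counts = np.round(counts).astype(np.int64)
    return PWM(probs, counts=int_counts, pseudocount=pseudocount)


def write_transfac(pwm: PWM, path, name: str = "motif") -> None:
    """TRANSFAC-style text export (counts if available, else probabilities)."""
    mat = pwm.counts if pwm.counts is not None else pwm.probs
    with open(path, "w") as fh:
        fh.write(f"ID {name}\nBF synthetic\nP0      A      C      G      T\n")
        for i, row in enumerate(mat, 1):
            cells = "  ".join(f"{v:>8.4f}" if isinstance(v, float) or mat is pwm.probs
                              else f"{int(v):>8d}" for v in row)
            fh.write(f"{i:02d}  {cells}\n")
        fh.write("XX\n//\n")


def read_matrix(path, pseudocount: float = 0.0) -> PWM:
    """Dispatch on extension: .tsv -> plain TSV, otherwise TRANSFAC/JASPAR."""
    if str(path).endswith(".tsv"):
        return read_pwm_tsv(path)
    return read_transfac(path, pseudocount)


def write_pwm_tsv(pwm: PWM, path) -> None:
    """Plain TSV export: one row per nucleotide (A, C, G, T), one column per
    motif position, probabilities."""
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(i) for i in range(1, pwm.width + 1)) + "\n")
        for a, letter in enumerate(ALPHABET):
            fh.write(
                letter + "\t"
                + "\t".join(f"{p:.12g}" for p in pwm.probs[:, a]) + "\n"
            )


def read_pwm_tsv(path) -> PWM:
    rows = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0] == "base" or not parts[0]:
                continue
            if parts[0] not in ALPHABET:
                raise ValueError(f"{path}:{ln}: unexpected row label {parts[0]!r}")
            rows[parts[0]] = [float(x) for x in parts[1:]]
    if set(rows) != set(ALPHABET):
        raise ValueError(f"{path}: need exactly rows A, C, G, T; got {sorted(rows)}")
    probs = np.array([rows[a] for a in ALPHABET]).T
    return PWM(probs)


# --------------------------------------------------------------------------
# consensus initialization


def consensus_to_pwm(iupac: str, match_prob: float = 0.8) -> PWM:
    """Build an initial PWM from an IUPAC consensus string.

    ``match_prob`` is split equally among the letters a degenerate code
    denotes; the remainder is split equally among the other letters.  ``N``
    gives a uniform column.
    """
    if not iupac:
        raise ValueError("empty consensus")
    if not 0.25 < match_prob <= 1.0:
        raise ValueError("match_prob must lie in (0.25, 1]")
    probs = np.zeros((len(iupac), 4))
    for i, ch in enumerate(iupac.upper()):
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC letter {ch!r} at position {i + 1}")
        members = [ALPHABET.index(a) for a in IUPAC_CODES[ch]]
        if len(members) == 4:
            probs[i] = 0.25
            continue
        rest = [a for a in range(4) if a not in members]
        probs[i, members] = match_prob / len(members)
        probs[i, rest] = (1.0 - match_prob) / len(rest)
    return PWM(probs)


# --------------------------------------------------------------------------
# TPWM JSON schema


def _pwm_payload(pwm: PWM | None):
    if pwm is None:
        return None
    return [[float(p) for p in row] for row in pwm.probs]


def _pwm_from_payload(payload, where: str) -> PWM | None:
    if payload is None:
        return None
    try:
        return PWM(np.asarray(payload, dtype=float))
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: invalid PWM payload: {exc}") from None


def tpwm_to_json(model: TPWM) -> dict:
    """Serialize a TPWM to a JSON-compatible document."""
    nodes = []
    for node in model.iter_nodes():
        nodes.append(
            {
                "id": node.node_id,
                "is_leaf": node.is_leaf,
                "n_sites": node.n_sites,
                "fixed": {str(p): ALPHABET[a] for p, a in node.fixed.items()},
                "split_position": node.split_position,
                "branch_probs": (
                    None if node.branch_probs is None
                    else [float(x) for x in node.branch_probs]
                ),
                "children": {
                    ALPHABET[a]: child.node_id for a, child in node.children.items()
                },
                "pwm": _pwm_payload(node.leaf_pwm),
                "fallback_pwm": _pwm_payload(node.fallback_pwm),
                "miss_mass": node.miss_mass,
            }
        )
    nodes.sort(key=lambda d: d["id"])
    return {
        "format_version": TPWM_JSON_VERSION,
        "width": model.width,
        "min_leaf": model.min_leaf,
        "dep_threshold": model.dep_threshold,
        "pseudocount": model.pseudocount,
        "root": model.root.node_id,
        "nodes": nodes,
    }


def tpwm_from_json(doc: dict) -> TPWM:
    """Rebuild a TPWM from its JSON document (strict: schema violations and
    version mismatches raise with the offending JSON path)."""
    if not isinstance(doc, dict):
        raise ValueError("$: TPWM document must be an object")
    version = doc.get("format_version")
    if version != TPWM_JSON_VERSION:
        raise ValueError(
            f"$.format_version: expected {TPWM_JSON_VERSION}, got {version!r}"
        )
    for key in ("width", "root", "nodes"):
        if key not in doc:
            raise ValueError(f"$.{key}: missing required field")
    width = int(doc["width"])
    nodes: dict[int, TPWMNode] = {}
    children_spec: dict[int, dict[int, int]] = {}
    for i, nd in enumerate(doc["nodes"]):
        where = f"$.nodes[{i}]"
        try:
            fixed = {
                int(p): ALPHABET.index(a) for p, a in (nd.get("fixed") or {}).items()
            }
            node = TPWMNode(
                node_id=int(nd["id"]),
                n_sites=int(nd["n_sites"]),
                fixed=fixed,
                is_leaf=bool(nd["is_leaf"]),
                split_position=nd.get("split_position"),
                branch_probs=(
                    None if nd.get("branch_probs") is None
                    else np.asarray(nd["branch_probs"], dtype=float)
                ),
                leaf_pwm=_pwm_from_payload(nd.get("pwm"), where + ".pwm"),
                fallback_pwm=_pwm_from_payload(
                    nd.get("fallback_pwm"), where + ".fallback_pwm"
                ),
                miss_mass=float(nd.get("miss_mass", 0.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{where}: {exc}") from None
        if node.node_id in nodes:
            raise ValueError(f"{where}.id: duplicate node id {node.node_id}")
        nodes[node.node_id] = node
        children_spec[node.node_id] = {
            ALPHABET.index(a): int(cid)
            for a, cid in (nd.get("children") or {}).items()
        }
    linked = set()
    for nid, spec in children_spec.items():
        for a, cid in spec.items():
            if cid not in nodes:
                raise ValueError(
                    f"$.nodes[id={nid}].children: unknown child node id {cid}"
                )
            nodes[nid].children[a] = nodes[cid]
            linked.add(cid)
    root_id = int(doc["root"])
    if root_id not in nodes:
        raise ValueError(f"$.root: unknown node id {root_id}")
    if root_id in linked:
        raise ValueError("$.root: root node is referenced as a child")
    return TPWM(
        width=width,
        root=nodes[root_id],
        min_leaf=int(doc.get("min_leaf", 0) or 0),
        dep_threshold=float(doc.get("dep_threshold", 0.0)),
        pseudocount=float(doc.get("pseudocount", 0.0)),
    )


def save_tpwm(model: TPWM, path) -> None:
    with open(path, "w") as fh:
        json.dump(tpwm_to_json(model), fh, indent=1)
        fh.write("\n")


def load_tpwm(path) -> TPWM:
    with open(path) as fh:
        return tpwm_from_json(json.load(fh))


def load_model(path, pseudocount: float = 0.0):
    """Load either a TPWM JSON document or a PWM matrix file by extension."""
    if str(path).endswith(".json"):
        return load_tpwm(path)
    return read_matrix(path, pseudocount)
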