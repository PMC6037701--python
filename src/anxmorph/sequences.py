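"""Annexin-family sequence pipeline: alignment, distances, dendrogram.

Reproducible pipeline over protein sequences: progressive multiple
alignment with a BLOSUM substitution matrix, Jukes-Cantor amino-acid
distances (20-state multiple-hit correction, pairwise deletion of gapped
sites), and agglomerative UPGMA/WPGMA clustering into an ultrametric
dendrogram with Newick output.  A seeded divergence simulator provides
ground-truth sequence sets for recovery tests, and also generates the
bundled synthetic stand-in for the 12 human annexins.

The human annexin family (ANXA1-ANXA11, ANXA13) shares a conserved
C-terminal core of four annexin repeats (eight in ANXA6, the only
double-core member) behind highly variable N-terminal regions.  Family
members with similar membrane phenotypes (blebbing/folding: ANXA1+ANXA2;
cooperative rolling: ANXA4+ANXA5; lens formation: ANXA7+ANXA11) are
mutual nearest neighbours in sequence space, and ANXA6 is the clear
outlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO

from .align import AA_ALPHABET, GAP, align_profiles, load_matrix

__all__ = [
    "SeqRecord",
    "Alignment",
    "DistanceMatrix",
    "Dendrogram",
    "Node",
    "ANNEXIN_ACCESSIONS",
    "load_annexin_fixtures",
    "multiple_align",
    "jukes_cantor_distance",
    "upgma",
    "sister_pairs",
    "simulate_divergence",
    "synthesize_annexin_family",
    "InfiniteDistanceError",
]

_VALID = set(AA_ALPHABET)

#: Protein-database accessions of the 12 human annexins (ANXA13 isoform b).
ANNEXIN_ACCESSIONS: Mapping[str, str] = {
    "ANXA1": "NP_000691",
    "ANXA2": "AAH68065",
    "ANXA3": "NP_005130",
    "ANXA4": "EAW99844",
    "ANXA5": "NP_001145",
    "ANXA6": "AAH17046",
    "ANXA7": "AAH02632",
    "ANXA8": "AAH73755",
    "ANXA9": "NP_003559",
    "ANXA10": "NP_009124",
    "ANXA11": "CAB94997",
    "ANXA13": "NP_001003954",
}

_FIXTURE_NAME = "annexins_human_synthetic.fasta"


class InfiniteDistanceError(ValueError):
    """Raised when observed divergence saturates the Jukes-Cantor correction."""


@dataclass(frozen=True)
class SeqRecord:
    """An amino-acid sequence with its taxon label and accession."""

    id: str
    residues: str
    accession: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _VALID
        if bad:
            raise ValueError(f"{self.id}: invalid residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows keyed by taxon id (input order preserved)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        for pos in range(len(self.rows[0])):
            if all(r[pos] == GAP for r in self.rows):
                raise ValueError(f"all-gap column at position {pos}")

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances over labelled taxa."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite and nonnegative")
        object.__setattr__(self, "d", m)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass(frozen=True)
class Node:
    """A dendrogram node; leaves have height 0 and carry the taxon label."""

    height: float
    name: str = ""
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.name
        else:
            body = "(" + ",".join(c._newick(self.height) for c in self.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:.6g}"


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric tree from pair-group average clustering."""

    root: Node
    method: str = "upgma"

    @property
    def labels(self) -> list[str]:
        return self.root.leaves()

    def newick(self) -> str:
        return self.root.newick()

    def cophenetic(self, a: str, b: str) -> float:
        """Distance implied by the tree: twice the height of the MRCA."""
        node = self.root
        while True:
            nxt = [c for c in node.children if a in c.leaves() and b in c.leaves()]
            if not nxt:
                return 2.0 * node.height
            node = nxt[0]


# ---------------------------------------------------------------------------
# fixtures


def load_annexin_fixtures() -> list[SeqRecord]:
    """Load the bundled 12-member annexin fixture set.

    The bundled FASTA is a *synthetic stand-in* for the database records:
    headers carry the real accessions for bookkeeping, but the residues
    were generated by :func:`synthesize_annexin_family` rather than
    fetched from the sequence databases.  Headers have the form
    ``ANXA1|NP_000691|synthetic``.
    """
    ref = resources.files("anxmorph").joinpath("data", _FIXTURE_NAME)
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise FileNotFoundError(
            "bundled annexin fixture missing; expected 12 records with "
            f"accessions {dict(ANNEXIN_ACCESSIONS)}"
        ) from exc
    from io import StringIO

    records = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        parts = rec.id.split("|")
        records.append(SeqRecord(id=parts[0], residues=str(rec.seq), accession=parts[1]))
    ids = [r.id for r in records]
    if sorted(ids) != sorted(ANNEXIN_ACCESSIONS) or len(set(ids)) != 12:
        raise ValueError(
            f"corrupt annexin fixture: got ids {ids}, expected {sorted(ANNEXIN_ACCESSIONS)}"
        )
    for r in records:
        if r.accession != ANNEXIN_ACCESSIONS[r.id]:
            raise ValueError(f"{r.id}: accession {r.accession} != {ANNEXIN_ACCESSIONS[r.id]}")
    return records


# ---------------------------------------------------------------------------
# multiple alignment


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """Fractional common k-mer distance used for the guide tree."""
    from collections import Counter

    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    common = sum((ca & cb).values())
    denom = min(sum(ca.values()), sum(cb.values()))
    return 1.0 - common / denom if denom else 1.0


def multiple_align(
    seqs: Iterable[SeqRecord],
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> Alignment:
    """Progressive multiple alignment.

    Pairwise k-mer distances (k=3) give a UPGMA guide tree; blocks are
    merged bottom-up by profile-profile global alignment under the named
    substitution matrix with affine gap scores (``gap_open`` for the first
    gap position, ``gap_extend`` for each further one; both negative).
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to align")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    mat = load_matrix(matrix)

    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _kmer_distance(seqs[i].residues, seqs[j].residues)
    guide = upgma(DistanceMatrix(labels=tuple(ids), d=dm))

    blocks: dict[str, tuple[list[str], list[str]]] = {
        s.id: ([s.id], [s.residues]) for s in seqs
    }

    def merge(node: Node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return blocks[node.name]
        left = merge(node.children[0])
        right = merge(node.children[1])
        ra, rb = align_profiles(left[1], right[1], mat, gap_open, gap_extend)
        return left[0] + right[0], ra + rb

    merged_ids, merged_rows = merge(guide.root)
    order = {tid: merged_rows[i] for i, tid in enumerate(merged_ids)}
    return Alignment(ids=tuple(ids), rows=tuple(order[i] for i in ids))


# ---------------------------------------------------------------------------
# distances


def jukes_cantor_distance(aligned: Alignment, complete_deletion: bool = False) -> DistanceMatrix:
    """Jukes-Cantor corrected amino-acid distances between aligned rows.

    For each pair, ``p`` is the fraction of differing sites among sites
    where both rows are ungapped (pairwise deletion; with
    ``complete_deletion`` only columns ungapped in every row are used),
    and ``d = -(19/20) ln(1 - (20/19) p)`` — the 20-state multiple-hit
    correction.  Saturated pairs (p >= 19/20) raise
    :class:`InfiniteDistanceError`.
    """
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aligned.rows]
    gap = GAP.encode()
    if complete_deletion:
        keep = np.ones(aligned.length, dtype=bool)
        for r in rows:
            keep &= r != gap
        rows = [r[keep] for r in rows]
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (rows[i] != gap) & (rows[j] != gap)
            n_sites = int(both.sum())
            if n_sites == 0:
                raise InfiniteDistanceError(
                    f"no comparable sites between {aligned.ids[i]} and {aligned.ids[j]}"
                )
            p = float(np.sum(rows[i][both] != rows[j][both])) / n_sites
            if p >= 19.0 / 20.0:
                raise InfiniteDistanceError(
                    f"saturated pair {aligned.ids[i]}/{aligned.ids[j]}: p = {p:.3f} >= 19/20"
                )
            d[i, j] = d[j, i] = -(19.0 / 20.0) * math.log(1.0 - (20.0 / 19.0) * p)
    return DistanceMatrix(labels=aligned.ids, d=d)


# ---------------------------------------------------------------------------
# clustering


def upgma(dist: DistanceMatrix, weighted: bool = False) -> Dendrogram:
    """Pair-group average agglomeration into an ultrametric dendrogram.

    Unweighted mode (UPGMA) averages inter-cluster distances with cluster
    sizes; weighted mode (WPGMA) averages the two branch distances
    plainly.  Merge height is half the merge distance.  Ties are broken
    by the lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest leaf), so the result is deterministic.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    d = {frozenset((i, j)): float(dist.d[i, j]) for i in range(n) for j in range(i + 1, n)}
    nodes: dict[int, Node] = {i: Node(height=0.0, name=lab) for i, lab in enumerate(dist.labels)}
    sizes = {i: 1 for i in range(n)}
    keys = {i: lab for i, lab in enumerate(dist.labels)}
    nxt = n
    while len(nodes) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], tuple(sorted((keys[i] for i in kv[0])))),
        )
        (pair, dij) = best
        i, j = sorted(pair)
        merged = Node(height=dij / 2.0, children=(nodes[i], nodes[j]))
        for k in list(nodes):
            if k in (i, j):
                continue
            dik, djk = d.pop(frozenset((i, k))), d.pop(frozenset((j, k)))
            if weighted:
                dnew = 0.5 * (dik + djk)
            else:
                dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            d[frozenset((nxt, k))] = dnew
        del d[pair]
        sizes[nxt] = sizes.pop(i) + sizes.pop(j)
        keys[nxt] = min(keys.pop(i), keys.pop(j))
        del nodes[i], nodes[j]
        nodes[nxt] = merged
        nxt += 1
    return Dendrogram(root=next(iter(nodes.values())), method="wpgma" if weighted else "upgma")


def sister_pairs(tree: Dendrogram) -> set[frozenset[str]]:
    """All cherries: unordered pairs of leaves sharing an immediate parent."""
    out: set[frozenset[str]] = set()

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        kids = node.children
        if len(kids) == 2 and all(c.is_leaf for c in kids):
            out.add(frozenset(c.name for c in kids))
        for c in kids:
            walk(c)

    walk(tree.root)
    return out


# ---------------------------------------------------------------------------
# divergence simulation


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator, n_states: int = 20) -> np.ndarray:
    """One Jukes-Cantor step: each site substitutes with the 20-state
    transition probability for branch length ``t`` (expected substitutions
    per site), drawing uniformly among the other residues."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    p_change = (n_states - 1) / n_states * (1.0 - math.exp(-n_states * t / (n_states - 1)))
    out = seq.copy()
    hit = rng.random(seq.size) < p_change
    if hit.any():
        shift = rng.integers(1, n_states, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % n_states
    return out


def _decode(idx: np.ndarray) -> str:
    return "".join(AA_ALPHABET[i] for i in idx)


def simulate_divergence(
    ancestor_length: int,
    tree_spec,
    seed: int,
) -> list[SeqRecord]:
    """Evolve a random ancestral sequence down a tree of branch lengths.

    ``tree_spec`` is a nested structure: a leaf is ``(name, branch_length)``
    and an internal node is ``([child, child, ...], branch_length)``
    (root branch length is ignored).  Branch lengths are expected
    substitutions per site under a uniform 20-state process, so pairwise
    Jukes-Cantor distances estimate path lengths.
    """
    if ancestor_length <= 0:
        raise ValueError("ancestor_length must be > 0")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 20, size=ancestor_length)
    out: list[SeqRecord] = []

    def walk(spec, seq: np.ndarray) -> None:
        payload, t = spec
        evolved = _evolve(seq, t, rng)
        if isinstance(payload, str):
            out.append(SeqRecord(id=payload, residues=_decode(evolved)))
        else:
            for child in payload:
                walk(child, evolved)

    walk((tree_spec[0], 0.0), ancestor)
    return out


# ---------------------------------------------------------------------------
# synthetic annexin family


def synthesize_annexin_family(seed: int = 20180709) -> list[SeqRecord]:
    """Generate the synthetic stand-in for the 12 human annexins.

    A 320-residue "core" evolves down an ultrametric family tree whose
    cherry structure mirrors the family's known similarity grouping
    ((ANXA1,ANXA2), (ANXA4,ANXA5), (ANXA7,ANXA11); ANXA6 most distant).
    Variable N-terminal regions are appended (shared evolved N-termini
    within cherries, short taxon-specific ones elsewhere), and ANXA6 gets
    a second, more diverged core copy, so full-length sequences have the
    lengths of the real proteins.  These residues are synthetic: they are
    not the database records named by the accessions.
    """
    rng = np.random.default_rng(seed)
    core = rng.integers(0, 20, size=320)

    # ultrametric core tree: (subtree_height -> branch = parent_h - h)
    tree = (
        [
            (
                [
                    (
                        [
                            ([("ANXA1", 0.20), ("ANXA2", 0.20)], 0.20),
                            ("ANXA9", 0.40),
                        ],
                        0.10,
                    ),
                    (
                        [
                            ([("ANXA4", 0.22), ("ANXA5", 0.22)], 0.20),
                            ("ANXA3", 0.42),
                        ],
                        0.08,
                    ),
                ],
                0.06,
            ),
            (
                [
                    (
                        [
                            ([("ANXA7", 0.25), ("ANXA11", 0.25)], 0.19),
                            ("ANXA8", 0.44),
                        ],
                        0.08,
                    ),
                    ("ANXA10", 0.52),
                ],
                0.04,
            ),
        ],
        0.04,
    )
    top = ([([tree, ("ANXA13", 0.60)], 0.10), ("ANXA6", 0.70)], 0.0)

    cores: dict[str, np.ndarray] = {}

    def walk(spec, seq: np.ndarray) -> None:
        payload, t = spec
        evolved = _evolve(seq, t, rng)
        if isinstance(payload, str):
            cores[payload] = evolved
        else:
            for child in payload:
                walk(child, evolved)

    walk(top, core)

    # N-terminal regions: cherries share an evolved ancestor
    nterm: dict[str, np.ndarray] = {}
    anc12 = rng.integers(0, 20, size=26)
    nterm["ANXA1"] = _evolve(anc12, 0.20, rng)
    nterm["ANXA2"] = _evolve(anc12, 0.20, rng)[:19]
    anc711 = rng.integers(0, 20, size=185)
    nterm["ANXA7"] = _evolve(anc711, 0.25, rng)[:168]
    nterm["ANXA11"] = _evolve(anc711, 0.25, rng)
    for name, ln in [
        ("ANXA3", 3), ("ANXA5", 1), ("ANXA8", 7), ("ANXA9", 25),
        ("ANXA10", 4), ("ANXA13", 37), ("ANXA6", 21),
    ]:
        nterm[name] = rng.integers(0, 20, size=ln)
    nterm["ANXA4"] = rng.integers(0, 20, size=0)

    records = []
    for name in ANNEXIN_ACCESSIONS:
        body = cores[name]
        if name == "ANXA4":
            body = body[1:]  # 319 residues, like the real protein
        parts = [nterm[name], body]
        if name == "ANXA6":
            linker = rng.integers(0, 20, size=12)
            second_core = _evolve(core, 0.9, rng)
            parts += [linker, second_core]
        seq = _decode(np.concatenate(parts))
        records.append(SeqRecord(id=name, residues=seq, accession=ANNEXIN_ACCESSIONS[name]))
    return records


def write_fasta(records: Iterable[SeqRecord], path, tag: str = "synthetic") -> None:
    """Write records as FASTA with ``id|accession|tag`` headers."""
    with open(path, "w") as fh:
        for r in records:
            header = f"{r.id}|{r.accession}" + (f"|{tag}" if tag else "")
            fh.write(f">{header}\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i : i + 60] + "\n")
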