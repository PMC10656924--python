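"""Global-identity alignment, greedy 97 % clustering, genome assignment.

The clustering bridges amplicon sequence variants (ASVs) and reference
genomes: ASVs are merged into OTU-like clusters at a global identity
threshold (0.97 by default), and each genome's 16S gene is assigned to
every cluster whose representative it matches at the same threshold.
Clusters then become the taxon units for pathway projection.

Identity is defined on a Needleman-Wunsch global alignment with match +1,
mismatch -1 and affine gaps (open -2, extend -1; a length-L gap costs
-2 - (L-1)), as matches / alignment length where gap columns count in the
denominator and N never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ParseError
from .io import DNA_ALPHABET

DEFAULT_THRESHOLD = 0.97


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    # ACGT match/mismatch +1/-1; N is never a match, even against N
    letters = "ACGTN"
    mat = substitution_matrices.Array(letters, dims=2)
    for a in letters:
        for b in letters:
            mat[a, b] = 1.0 if (a == b and a != "N") else -1.0
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def _check_seq(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ParseError(f"empty {name}")
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ParseError(f"{name} contains non-ACGTN symbols: {sorted(bad)}")
    return s


def global_alignment(seq_a: str, seq_b: str):
    """Best-scoring global alignment (deterministic first traceback)."""
    a = _check_seq(seq_a, "seq_a")
    b = _check_seq(seq_b, "seq_b")
    return _ALIGNER.align(a, b)[0]


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in the optimal global alignment.

    Gap columns count in the denominator; columns involving N never count
    as identical.  Symmetric, and 1.0 for identical N-free sequences.
    """
    aln = global_alignment(seq_a, seq_b)
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x not in ("-", "N")
    )
    return matches / len(row_a)


@dataclass
class ClusterMap:
    """ASV -> cluster assignments at a fixed identity threshold, with per-
    cluster representative sequences and (optionally) matched genomes."""

    cluster_of_asv: dict[str, str]
    representative: dict[str, str]           # cluster -> representative ASV id
    representative_seq: dict[str, str]       # cluster -> representative sequence
    threshold: float
    genomes_of: dict[str, list[str]] = field(default_factory=dict)
    unassigned_genomes: list[str] = field(default_factory=list)

    def validate(self) -> "ClusterMap":
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0.5, 1]")
        for c, rep in self.representative.items():
            if self.cluster_of_asv.get(rep) != c:
                raise ValueError(f"representative {rep} not in its cluster {c}")
        return self

    @property
    def clusters(self) -> list[str]:
        return list(self.representative)

    def members(self, cluster: str) -> list[str]:
        return [a for a, c in self.cluster_of_asv.items() if c == cluster]


def greedy_cluster(
    seqs: list[tuple[str, str]], threshold: float = DEFAULT_THRESHOLD
) -> ClusterMap:
    """cd-hit-style greedy incremental clustering.

    Sequences are visited by decreasing length (ties broken by id); each
    joins the first-founded cluster whose representative it matches at
    >= ``threshold`` global identity, else founds a new cluster.  The
    declared visit order makes the result independent of input order.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    ordered = sorted(seqs, key=lambda r: (-len(r[1]), r[0]))
    cluster_of: dict[str, str] = {}
    reps: list[tuple[str, str, str]] = []  # (cluster id, rep asv id, rep seq)
    for sid, seq in ordered:
        seq = _check_seq(seq, f"sequence {sid}")
        home = None
        for cid, rep_id, rep_seq in reps:
            if global_identity(seq, rep_seq) >= threshold:
                home = cid
                break
        if home is None:
            home = f"c{len(reps):04d}"
            reps.append((home, sid, seq))
        cluster_of[sid] = home
    return ClusterMap(
        cluster_of_asv=cluster_of,
        representative={cid: rep_id for cid, rep_id, _ in reps},
        representative_seq={cid: rep_seq for cid, _, rep_seq in reps},
        threshold=threshold,
    ).validate()


def assign_genomes(
    genome_seqs: list[tuple[str, str]],
    cmap: ClusterMap,
    threshold: float | None = None,
) -> ClusterMap:
    """Assign each genome 16S sequence to every cluster whose representative
    it matches at >= threshold; genomes matching none are recorded in
    ``unassigned_genomes``.  Returns ``cmap`` with ``genomes_of`` filled."""
    thr = cmap.threshold if threshold is None else threshold
    genomes_of: dict[str, list[str]] = {c: [] for c in cmap.clusters}
    unassigned: list[str] = []
    for gid, seq in genome_seqs:
        seq = _check_seq(seq, f"genome {gid}")
        hit = False
        for cid, rep_seq in cmap.representative_seq.items():
            if global_identity(seq, rep_seq) >= thr:
                genomes_of[cid].append(gid)
                hit = True
        if not hit:
            unassigned.append(gid)
    cmap.genomes_of = genomes_of
    cmap.unassigned_genomes = unassigned
    return cmap
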