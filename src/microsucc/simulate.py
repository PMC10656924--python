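"""Synthetic recolonization experiments with known ground truth.

The generator emulates the study design this package analyses: three source
communities (inocula bL, bJ, bA from larvae, juveniles and adult polyps)
applied to two substrates — live polyps and inert silicone tubes — and
sampled at 2, 7, 14 and 28 days post recolonization (dpr) with replicates,
plus one sample per inoculum.

The planted structure mirrors the phenomena downstream stages must detect:

* on **polyps** every taxon follows its colonizer-class trajectory (early
  taxa peak at 2–7 dpr, late taxa at 14–28 dpr) *regardless of inoculum* —
  the host-driven reset;
* on **tubes** community composition stays close to the inoculum pool over
  time — inoculum-driven assembly;
* metabolic pathways can be planted as early- or late-associated: taxa of
  the matching colonizer class carry them with elevated probability;
* 16S sequence families are generated with controlled within- and
  between-cluster identity so 97 % clustering has a known answer.

Counts are Dirichlet-multinomial around the trajectory means, which gives
replicate-level overdispersion beyond plain multinomial sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import io as msio
from .errors import SimulationError
from .io import CommunityTable, PathwayPresence, INOCULA, POST_TIMEPOINTS

COLONIZER_CLASSES = ("early", "late", "inoculum_specific")
PATHWAY_CLASSES = ("early_associated", "late_associated", "neutral")

#: scaled abundance of each colonizer class over (2, 7, 14, 28) dpr.
#: Early taxa start at ~6x the per-taxon weight of late taxa at 2 dpr and
#: the ratio inverts by 28 dpr (comfortably above the 3x separation the
#: recovery benchmarks assume).
CLASS_TIME_WEIGHTS = {
    "early": (6.0, 4.0, 1.5, 1.0),
    "late": (1.0, 1.5, 4.0, 6.0),
    "inoculum_specific": (0.6, 0.6, 0.6, 0.6),
}

EARLY_SUBSYSTEMS = ("carbohydrate degradation", "chitin degradation")
LATE_SUBSYSTEMS = ("nitrogen cycle", "sulfur cycle")
NEUTRAL_SUBSYSTEMS = (
    "amino acid biosynthesis",
    "cofactor biosynthesis",
    "lipid metabolism",
    "energy metabolism",
    "nucleotide metabolism",
    "fermentation",
)


@dataclass
class TruthSpec:
    """Ground truth for one synthetic experiment.

    ``trajectory`` maps (substrate, inoculum) to a taxa x timepoint table of
    expected relative abundances (columns: "inoculum", 2, 7, 14, 28); every
    column sums to 1.  ``overdispersion`` is the Dirichlet concentration:
    larger values mean tighter replicates, ``None``/inf disables replicate
    noise entirely.  ``effect_size`` is the fraction of the headroom
    (1 - base_p) by which an associated pathway's presence probability is
    raised in its matching colonizer class.
    """

    n_taxa: int
    class_of: dict[str, str]
    inoculum_pools: dict[str, list[str]]
    trajectory: dict[tuple[str, str], pd.DataFrame]
    pathway_truth: dict[str, str]
    subsystem_of: dict[str, str]
    genome_of_taxon: dict[str, str | None]
    effect_size: float
    base_p: float
    overdispersion: float | None
    seed: int

    @property
    def taxa(self) -> list[str]:
        return list(self.class_of)

    def validate(self) -> "TruthSpec":
        if not 0 < self.effect_size <= 1:
            raise SimulationError("effect_size must be in (0, 1]")
        for key, traj in self.trajectory.items():
            sums = traj.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise SimulationError(
                    f"trajectory columns for {key} do not sum to 1: {dict(sums)}"
                )
        return self


@dataclass
class SyntheticExperiment:
    """Bundle of everything one synthetic run produces."""

    table: CommunityTable
    pathways: PathwayPresence  # rows are genome ids
    asv_seqs: list[tuple[str, str]]
    genome_seqs: list[tuple[str, str]]
    truth: TruthSpec


def default_truth(
    seed: int = 0,
    n_taxa: int = 80,
    n_pathways: int = 100,
    frac_early: float = 0.4,
    frac_late: float = 0.4,
    frac_associated: float = 0.1,
    effect_size: float = 0.6,
    base_p: float = 0.3,
    overdispersion: float | None = 200.0,
    genome_fraction: float = 0.9,
) -> TruthSpec:
    """Build the default planted truth used throughout the test surface.

    10 % of pathways are planted early-associated and 10 % late-associated
    (``frac_associated`` each); taxa without a genome (1 - genome_fraction)
    leave a realistic unmatched community fraction for coverage accounting.
    """
    rng = np.random.default_rng(seed)
    taxa = [f"asv{i:03d}" for i in range(n_taxa)]
    n_early = int(round(frac_early * n_taxa))
    n_late = min(int(round(frac_late * n_taxa)), n_taxa - n_early)
    # early and late classes are built as weight-matched pairs: the late
    # class reuses the early class's weight multiset, so for symmetric
    # class trajectories a pathway carried by both members of a rank pair
    # has exactly the same expected abundance in early and late samples
    n_pairs = min(n_early, n_late)
    n_early = n_late = n_pairs
    classes = (
        ["early"] * n_early
        + ["late"] * n_late
        + ["inoculum_specific"] * (n_taxa - n_early - n_late)
    )
    perm = rng.permutation(n_taxa)
    class_by_idx = dict(zip(perm, classes))
    class_of = {t: class_by_idx[i] for i, t in enumerate(taxa)}

    # per-taxon base weight: mild lognormal spread so no taxon dominates
    weight = pd.Series(np.exp(rng.normal(0.0, 0.5, size=n_taxa)), index=taxa)
    early_taxa = [t for t in taxa if class_of[t] == "early"]
    late_taxa = [t for t in taxa if class_of[t] == "late"]
    weight[late_taxa] = np.sort(weight[early_taxa].to_numpy())[::-1]
    weight[early_taxa] = np.sort(weight[early_taxa].to_numpy())[::-1]

    # inoculum pools: each inoculum-specific taxon belongs to exactly one
    # pool; early/late taxa are shared across pools with prob 0.7
    specific = [t for t in taxa if class_of[t] == "inoculum_specific"]
    pools: dict[str, list[str]] = {inoc: [] for inoc in INOCULA}
    for k, t in enumerate(specific):
        pools[INOCULA[k % len(INOCULA)]].append(t)
    for t in taxa:
        if class_of[t] == "inoculum_specific":
            continue
        for inoc in INOCULA:
            if rng.random() < 0.7:
                pools[inoc].append(t)
    for inoc in INOCULA:
        if not pools[inoc]:  # degenerate tiny-n guard
            pools[inoc].append(taxa[0])

    trajectory: dict[tuple[str, str], pd.DataFrame] = {}
    cols = ["inoculum", *POST_TIMEPOINTS]
    for inoc in INOCULA:
        member = pd.Series(
            [1.0 if t in set(pools[inoc]) else 0.0 for t in taxa], index=taxa
        )
        inoc_profile = weight * member
        inoc_profile /= inoc_profile.sum()
        # polyp: host-driven — class trajectories, identical across inocula
        polyp = pd.DataFrame(index=taxa, columns=cols, dtype=float)
        polyp["inoculum"] = inoc_profile
        for j, tp in enumerate(POST_TIMEPOINTS):
            w = weight * pd.Series(
                [CLASS_TIME_WEIGHTS[class_of[t]][j] for t in taxa], index=taxa
            )
            polyp[tp] = w / w.sum()
        trajectory[("polyp", inoc)] = polyp
        # tube: inoculum-driven — the pool profile persists over time
        tube = pd.DataFrame(
            np.tile(inoc_profile.to_numpy()[:, None], (1, len(cols))),
            index=taxa,
            columns=cols,
        )
        trajectory[("tube", inoc)] = tube

    pathways = [f"pwy{i:03d}" for i in range(n_pathways)]
    n_assoc = int(round(frac_associated * n_pathways))
    pathway_truth: dict[str, str] = {}
    subsystem_of: dict[str, str] = {}
    for i, p in enumerate(pathways):
        if i < n_assoc:
            pathway_truth[p] = "early_associated"
            subsystem_of[p] = EARLY_SUBSYSTEMS[i % len(EARLY_SUBSYSTEMS)]
        elif i < 2 * n_assoc:
            pathway_truth[p] = "late_associated"
            subsystem_of[p] = LATE_SUBSYSTEMS[i % len(LATE_SUBSYSTEMS)]
        else:
            pathway_truth[p] = "neutral"
            subsystem_of[p] = NEUTRAL_SUBSYSTEMS[i % len(NEUTRAL_SUBSYSTEMS)]

    # genome presence is decided per early/late rank pair (both or neither)
    # so dropping a genome never unbalances a pair; stage-neutral taxa are
    # independent
    genome_of_taxon: dict[str, str | None] = {t: None for t in taxa}
    for te, tl in zip(early_taxa, late_taxa):
        if rng.random() < genome_fraction:
            genome_of_taxon[te] = f"genome_{te}"
            genome_of_taxon[tl] = f"genome_{tl}"
    for t in taxa:
        if class_of[t] == "inoculum_specific" and rng.random() < genome_fraction:
            genome_of_taxon[t] = f"genome_{t}"

    return TruthSpec(
        n_taxa=n_taxa,
        class_of=class_of,
        inoculum_pools=pools,
        trajectory=trajectory,
        pathway_truth=pathway_truth,
        subsystem_of=subsystem_of,
        genome_of_taxon=genome_of_taxon,
        effect_size=effect_size,
        base_p=base_p,
        overdispersion=overdispersion,
        seed=seed,
    ).validate()


def _sample_counts(
    rng: np.random.Generator, p: np.ndarray, depth: int, concentration: float | None
) -> np.ndarray:
    """One Dirichlet-multinomial draw around mean proportions ``p``."""
    support = p > 0
    q = np.zeros_like(p)
    if concentration is None or not np.isfinite(concentration):
        q[support] = p[support]
    else:
        q[support] = rng.dirichlet(concentration * p[support])
    out = np.zeros(p.shape[0], dtype=np.int64)
    out[support] = rng.multinomial(depth, q[support] / q[support].sum())
    return out


def generate_experiment(
    spec: TruthSpec, n_replicates: int = 5, depth: int = 20_000
) -> SyntheticExperiment:
    """Draw the full experiment: counts, pathway presence, 16S sequences.

    Sample layout: 2 substrates x 3 inocula x 4 timepoints x ``n_replicates``
    recolonization samples plus one sample per inoculum.  Identical
    (spec, seed) inputs give bit-identical outputs.
    """
    if depth < 100:
        raise SimulationError("depth must be >= 100")
    if n_replicates < 2:
        raise SimulationError("n_replicates must be >= 2")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    taxa = spec.taxa

    rows, meta_rows, ids = [], [], []
    for inoc in INOCULA:
        traj = spec.trajectory[("polyp", inoc)].loc[taxa]
        p = traj["inoculum"].to_numpy()
        ids.append(f"inoc_{inoc}")
        rows.append(_sample_counts(rng, p, depth, spec.overdispersion))
        meta_rows.append(("polyp", inoc, "inoculum", 1))
    for substrate in ("polyp", "tube"):
        for inoc in INOCULA:
            traj = spec.trajectory[(substrate, inoc)].loc[taxa]
            for tp in POST_TIMEPOINTS:
                p = traj[tp].to_numpy()
                for rep in range(1, n_replicates + 1):
                    ids.append(f"{substrate}_{inoc}_d{tp:02d}_r{rep}")
                    rows.append(_sample_counts(rng, p, depth, spec.overdispersion))
                    meta_rows.append((substrate, inoc, tp, rep))

    counts = pd.DataFrame(np.vstack(rows), index=ids, columns=taxa)
    meta = pd.DataFrame(
        meta_rows, index=ids, columns=["substrate", "inoculum", "timepoint", "replicate"]
    )
    table = CommunityTable(counts=counts, meta=meta).validate()

    # pathway presence per genome.  Associated pathways: independent
    # Bernoulli draws, with the matching colonizer class enriched by
    # effect_size of the headroom above base_p.  Neutral pathways: carriers
    # are drawn in early/late weight-matched pairs (both members or
    # neither), so their carried abundance is balanced across stages by
    # construction and planted neutrality is the realized truth.
    genomes = [g for g in spec.genome_of_taxon.values() if g is not None]
    taxon_of_genome = {
        g: t for t, g in spec.genome_of_taxon.items() if g is not None
    }
    p_assoc = spec.base_p + spec.effect_size * (1.0 - spec.base_p)
    ref_abund = spec.trajectory[("polyp", INOCULA[0])][POST_TIMEPOINTS[0]]
    by_class: dict[str, list[int]] = {"early": [], "late": [], "inoculum_specific": []}
    for i, g in enumerate(genomes):
        by_class[spec.class_of[taxon_of_genome[g]]].append(i)
    weight_of = lambda i: float(ref_abund[taxon_of_genome[genomes[i]]])
    early_sorted = sorted(by_class["early"], key=weight_of, reverse=True)
    late_sorted = sorted(by_class["late"], key=weight_of, reverse=True)
    n_pairs = min(len(early_sorted), len(late_sorted))
    pairs = list(zip(early_sorted[:n_pairs], late_sorted[:n_pairs]))
    # unpaired early/late genomes would carry a one-sided stage signal, so
    # neutral pathways are carried only by pairs and stage-neutral taxa
    singles = by_class["inoculum_specific"]
    pres = np.zeros((len(genomes), len(spec.pathway_truth)), dtype=np.int8)
    pw_ids = list(spec.pathway_truth)
    for j, pw in enumerate(pw_ids):
        truth = spec.pathway_truth[pw]
        if truth == "neutral":
            for a, b in pairs:
                if rng.random() < spec.base_p:
                    pres[a, j] = pres[b, j] = 1
            for i in singles:
                pres[i, j] = rng.random() < spec.base_p
        else:
            match_class = "early" if truth == "early_associated" else "late"
            for i, g in enumerate(genomes):
                cls = spec.class_of[taxon_of_genome[g]]
                prob = p_assoc if cls == match_class else spec.base_p
                pres[i, j] = rng.random() < prob
    pathways = PathwayPresence(
        presence=pd.DataFrame(pres, index=genomes, columns=pw_ids),
        subsystem_of=dict(spec.subsystem_of),
    ).validate()

    # one 16S family per taxon: the ASV and (if present) the genome's 16S
    # gene are independent mutants of the taxon ancestor
    anc_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    ancestors, _ = _cluster_ancestors(anc_rng, len(taxa), 0.90, 400)
    asv_seqs, genome_seqs = [], []
    for t, anc in zip(taxa, ancestors):
        asv_seqs.append((t, _mutate(anc_rng, anc, 0.005)))
        g = spec.genome_of_taxon[t]
        if g is not None:
            genome_seqs.append((g, _mutate(anc_rng, anc, 0.005)))

    return SyntheticExperiment(
        table=table,
        pathways=pathways,
        asv_seqs=asv_seqs,
        genome_seqs=genome_seqs,
        truth=spec,
    )


# ---------------------------------------------------------------------------
# sequence families

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate_arr(
    rng: np.random.Generator, seq: np.ndarray, rate: float
) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.shape[0]) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    return _to_str(_mutate_arr(rng, np.frombuffer(seq.encode(), dtype=np.uint8), rate))


def _cluster_ancestors(
    rng: np.random.Generator, n_clusters: int, between_identity: float, length: int
) -> tuple[list[str], np.ndarray]:
    root = _random_seq(rng, length)
    ancs = [
        _to_str(_mutate_arr(rng, root, 1.0 - between_identity))
        for _ in range(n_clusters)
    ]
    return ancs, root


def generate_sequences(
    n_clusters: int,
    members_per_cluster: int,
    within_identity: float = 0.99,
    between_identity: float = 0.90,
    length: int = 1000,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Sequence families with controlled identity structure.

    Each cluster ancestor is a copy of a common root mutated at per-site
    rate (1 - between_identity); members mutate their ancestor at rate
    (1 - within_identity).  Returns (records, true cluster label per id).
    """
    if not 0 < between_identity < within_identity <= 1:
        raise SimulationError(
            "require 0 < between_identity < within_identity <= 1, got "
            f"between={between_identity}, within={within_identity}"
        )
    rng = np.random.default_rng(seed)
    ancestors, _ = _cluster_ancestors(rng, n_clusters, between_identity, length)
    records: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for c, anc in enumerate(ancestors):
        cname = f"cluster{c:03d}"
        for m in range(members_per_cluster):
            sid = f"{cname}_m{m:02d}"
            records.append((sid, _mutate(rng, anc, 1.0 - within_identity)))
            labels[sid] = cname
    return records, labels


# ---------------------------------------------------------------------------
# on-disk layout


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> dict[str, str]:
    """Write counts.tsv, meta.tsv, pathways.tsv, subsystems.tsv, asv.fasta,
    genomes_16s.fasta and truth.json under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: str(outdir / v) for k, v in {
        "counts": "counts.tsv",
        "meta": "meta.tsv",
        "pathways": "pathways.tsv",
        "subsystems": "subsystems.tsv",
        "asv_fasta": "asv.fasta",
        "genomes_fasta": "genomes_16s.fasta",
        "truth": "truth.json",
    }.items()}
    msio.write_community_table(exp.table, paths["counts"], paths["meta"])
    msio.write_pathway_presence(exp.pathways, paths["pathways"], paths["subsystems"])
    msio.write_fasta(exp.asv_seqs, paths["asv_fasta"])
    msio.write_fasta(exp.genome_seqs, paths["genomes_fasta"])
    truth = exp.truth
    payload = {
        "seed": truth.seed,
        "n_taxa": truth.n_taxa,
        "effect_size": truth.effect_size,
        "base_p": truth.base_p,
        "overdispersion": truth.overdispersion,
        "class_of": truth.class_of,
        "inoculum_pools": truth.inoculum_pools,
        "pathway_truth": truth.pathway_truth,
        "subsystem_of": truth.subsystem_of,
        "genome_of_taxon": truth.genome_of_taxon,
        "asv_cluster": {t: t for t in truth.taxa},
    }
    Path(paths["truth"]).write_text(json.dumps(payload, indent=1))
    return paths
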