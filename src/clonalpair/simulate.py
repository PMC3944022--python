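"""Synthetic paired-tumor cohorts with known ground truth.

The generator emulates the statistical structure of a 15-patient cohort of
primary colorectal tumors and matched liver metastases:

* *clonally related* pairs share a trunk of mutations acquired before the
  metastatic lineage diverged (about 30-55% of the union at the defaults),
  always including at least one driver-panel mutation, plus private
  mutations in each sample;
* *unrelated* pairs have disjoint mutation sets (no shared keys, by
  construction) with independently drawn driver mutations;
* a subset of metastases are *hypermutators*: private burden multiplied by
  ``hypermutator_multiplier`` (landing near 900 mutations at the defaults,
  against a ~30-70 baseline), at least one planted missense mutation in a
  mismatch-repair gene and one in a DNA-polymerase gene, and a copy-neutral
  LOH segment count drawn around ``loh_hypermutator_mean`` instead of
  ``loh_baseline_mean``;
* SCNA profiles are per-bin copy-number states on a toy genome; a related
  pair shares a base profile with per-bin discordance ``scna_noise_rate``,
  unrelated samples draw independent profiles.

Mutation positions are drawn without replacement from the whole toy genome,
so two samples share a key only when the generator plants it — truth labels
are exact, not probabilistic.  All randomness flows through one
``numpy.random.Generator`` in a fixed draw order: the same config (including
seed) yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .clonality import classify_pair, summarize_cohort
from .clustering import cohort_adjacency, hierarchical_cluster, pairwise_distance
from .concordance import cohort_concordance
from .hypermutation import annotate_panel_hits, call_hypermutated
from .io_formats import (
    CohortManifest,
    MutationRecord,
    PatientPair,
    SegmentRecord,
    write_manifest,
    write_mutation_table,
    write_segment_table,
)
from .panels import DRIVER_PANEL, MISMATCH_REPAIR_PANEL, POLYMERASE_PANEL, GenePanel
from .scna import build_cnv_matrix, summarize_cohort_scna

_BASES = "ACGT"

# Copy-number states drawn for an altered bin, with weights.
_EVENT_STATES = np.array([0, 1, 3, 4, 5])
_EVENT_WEIGHTS = np.array([0.05, 0.30, 0.45, 0.15, 0.05])

_SNV_EFFECTS = np.array(
    ["nonsynonymous", "synonymous", "stopgain", "stoploss", "splicing"]
)
_SNV_EFFECT_WEIGHTS = np.array([0.55, 0.30, 0.05, 0.02, 0.08])
_INDEL_EFFECTS = np.array(["frameshift_indel", "nonframeshift_indel"])


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults emulate the reference cohort's scale."""

    n_pairs: int = 15
    fraction_related: float = 8 / 15
    trunk_mutations_mean: float = 40.0
    private_mutations_mean: float = 30.0
    hypermutator_probability: float = 4 / 15
    hypermutator_multiplier: float = 30.0
    loh_baseline_mean: float = 15.0
    loh_hypermutator_mean: float = 150.0
    loh_dispersion_baseline: float = 1.5
    loh_dispersion_hyper: float = 50.0
    scna_bins: int = 500
    scna_event_rate: float = 0.2
    scna_noise_rate: float = 0.02
    indel_fraction: float = 0.08
    driver_rate_unrelated: float = 0.4
    plant_discordant_drivers: bool = False
    n_chromosomes: int = 5
    chromosome_length: int = 10_000_000
    n_background_genes: int = 2000
    driver_panel: GenePanel = DRIVER_PANEL
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "fraction_related",
            "hypermutator_probability",
            "scna_event_rate",
            "scna_noise_rate",
            "indel_fraction",
            "driver_rate_unrelated",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.hypermutator_multiplier <= 1:
            raise ValueError("hypermutator_multiplier must be > 1")
        if self.trunk_mutations_mean < 0 or self.private_mutations_mean < 0:
            raise ValueError("mutation means must be >= 0")
        genome = self.n_chromosomes * self.chromosome_length
        expected = self.n_pairs * 2 * (
            self.trunk_mutations_mean
            + self.private_mutations_mean * self.hypermutator_multiplier
        )
        if expected > genome / 100:
            raise ValueError(
                "toy genome too small for the configured mutation load; "
                "increase chromosome_length or lower the means"
            )
        if self.loh_hypermutator_mean > 0.6 * self.scna_bins:
            raise ValueError("loh_hypermutator_mean too large for scna_bins")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chromosome_length for i in range(self.n_chromosomes)
        }

    @property
    def bin_size(self) -> int:
        total = self.n_chromosomes * self.chromosome_length
        return max(1, total // self.scna_bins)


@dataclass
class TruthLabels:
    """Planted ground truth, recomputable from the emitted tables."""

    related: dict[str, bool]
    hypermutator: dict[str, bool]  # keyed by metastasis sample id
    trunk_size: dict[str, int]
    driver_genes: dict[str, frozenset[str]]  # trunk drivers per related patient
    mutation_counts: dict[str, int]  # per sample


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    mutations: list[MutationRecord]
    segments: list[SegmentRecord]
    manifest: CohortManifest
    truth: TruthLabels

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the three pipeline inputs plus a truth TSV; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mutations": outdir / "mutations.tsv",
            "segments": outdir / "segments.tsv",
            "manifest": outdir / "manifest.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_mutation_table(self.mutations, paths["mutations"])
        write_segment_table(self.segments, paths["segments"])
        write_manifest(self.manifest, paths["manifest"])
        with open(paths["truth"], "w") as fh:
            fh.write("patient\trelated\thypermutator_metastasis\ttrunk_size\n")
            for pair in self.manifest:
                pid = pair.patient_id
                fh.write(
                    f"{pid}\t{int(self.truth.related[pid])}\t"
                    f"{int(self.truth.hypermutator[pair.metastasis_sample_id])}\t"
                    f"{self.truth.trunk_size[pid]}\n"
                )
        return paths


class _KeyFactory:
    """Draws globally unique mutation keys from the toy genome."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def _locus(self) -> tuple[str, int]:
        while True:
            chrom = f"chr{int(self.rng.integers(1, self.config.n_chromosomes + 1))}"
            pos = int(self.rng.integers(1, self.config.chromosome_length + 1))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos

    def substitution(self, gene: str, effect: str | None = None) -> MutationRecord:
        chrom, pos = self._locus()
        ref = _BASES[int(self.rng.integers(4))]
        alt = ref
        while alt == ref:
            alt = _BASES[int(self.rng.integers(4))]
        if effect is None:
            effect = str(self.rng.choice(_SNV_EFFECTS, p=_SNV_EFFECT_WEIGHTS))
        return MutationRecord("", chrom, pos, ref, alt, gene, effect)

    def indel(self, gene: str) -> MutationRecord:
        chrom, pos = self._locus()
        base = _BASES[int(self.rng.integers(4))]
        if self.rng.random() < 0.5:
            ref, alt = base, "-"
        else:
            ref, alt = "-", base
        effect = str(self.rng.choice(_INDEL_EFFECTS))
        return MutationRecord("", chrom, pos, ref, alt, gene, effect)

    def background(self) -> MutationRecord:
        gene = f"G{int(self.rng.integers(1, self.config.n_background_genes + 1)):04d}"
        if self.rng.random() < self.config.indel_fraction:
            return self.indel(gene)
        return self.substitution(gene)


def _for_sample(records: Sequence[MutationRecord], sample_id: str):
    return [replace(r, sample_id=sample_id) for r in records]


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _base_profile(
    config: SimulationConfig, rng: np.random.Generator, n_bins: int, loh_mean: float,
    loh_dispersion: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin copy-number states and LOH flags for one independent profile."""
    cn = np.full(n_bins, 2, dtype=int)
    altered = rng.random(n_bins) < config.scna_event_rate
    cn[altered] = rng.choice(_EVENT_STATES, size=int(altered.sum()), p=_EVENT_WEIGHTS)
    loh = np.zeros(n_bins, dtype=bool)
    neutral = np.flatnonzero(cn == 2)
    n_loh = min(_negbin(rng, loh_mean, loh_dispersion), len(neutral))
    if n_loh:
        loh[rng.choice(neutral, size=n_loh, replace=False)] = True
    return cn, loh


def _add_loh(
    rng: np.random.Generator, cn: np.ndarray, loh: np.ndarray, extra: int
) -> None:
    free = np.flatnonzero((cn == 2) & ~loh)
    extra = min(extra, len(free))
    if extra > 0:
        loh[rng.choice(free, size=extra, replace=False)] = True


def _profile_segments(
    sample_id: str,
    cn: np.ndarray,
    loh: np.ndarray,
    bins: list[tuple[str, int, int]],
) -> list[SegmentRecord]:
    out = []
    for j, (chrom, start, end) in enumerate(bins):
        if cn[j] != 2 or loh[j]:
            out.append(
                SegmentRecord(sample_id, chrom, start, end, int(cn[j]), bool(loh[j]))
            )
    return out


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one cohort of paired samples with exact truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    keys = _KeyFactory(config, rng)

    from .scna import make_bins

    bins = make_bins(config.chrom_lengths, config.bin_size)
    n_bins = len(bins)

    n_related = round(config.n_pairs * config.fraction_related)
    related_flags = np.zeros(config.n_pairs, dtype=bool)
    related_flags[rng.permutation(config.n_pairs)[:n_related]] = True

    patients: list[PatientPair] = []
    mutations: list[MutationRecord] = []
    segments: list[SegmentRecord] = []
    truth = TruthLabels(
        related={}, hypermutator={}, trunk_size={}, driver_genes={},
        mutation_counts={},
    )
    driver_genes = sorted(config.driver_panel.genes)

    for i in range(config.n_pairs):
        pid = f"P{i + 1:03d}"
        pri, met = f"{pid}-PRI", f"{pid}-MET"
        patients.append(PatientPair(pid, pri, met))
        is_related = bool(related_flags[i])
        is_hyper = rng.random() < config.hypermutator_probability
        truth.related[pid] = is_related
        truth.hypermutator[met] = is_hyper

        # --- mutations ---------------------------------------------------
        met_private_mean = config.private_mutations_mean * (
            config.hypermutator_multiplier if is_hyper else 1.0
        )
        if is_related:
            n_trunk = int(rng.poisson(config.trunk_mutations_mean))
            trunk = [keys.background() for _ in range(n_trunk)]
            n_drv = int(rng.integers(1, 4))
            planted = [
                keys.substitution(g, effect="nonsynonymous")
                for g in rng.choice(driver_genes, size=n_drv, replace=False)
            ]
            trunk.extend(planted)
            truth.driver_genes[pid] = frozenset(m.gene for m in planted)
            truth.trunk_size[pid] = len(trunk)
            pri_muts = list(trunk)
            met_muts = list(trunk)
            if config.plant_discordant_drivers:
                gene = str(rng.choice(driver_genes))
                pri_muts.append(keys.substitution(gene, effect="nonsynonymous"))
                met_muts.append(keys.substitution(gene, effect="nonsynonymous"))
            for _ in range(int(rng.poisson(config.private_mutations_mean))):
                pri_muts.append(keys.background())
            for _ in range(int(rng.poisson(met_private_mean))):
                met_muts.append(keys.background())
        else:
            truth.driver_genes[pid] = frozenset()
            truth.trunk_size[pid] = 0
            per_sample_mean = config.trunk_mutations_mean + config.private_mutations_mean
            pri_muts = [
                keys.background() for _ in range(int(rng.poisson(per_sample_mean)))
            ]
            met_mean = (
                config.trunk_mutations_mean + met_private_mean
                if is_hyper
                else per_sample_mean
            )
            met_muts = [keys.background() for _ in range(int(rng.poisson(met_mean)))]
            for sample_muts in (pri_muts, met_muts):
                if rng.random() < config.driver_rate_unrelated:
                    gene = str(rng.choice(driver_genes))
                    sample_muts.append(keys.substitution(gene, effect="nonsynonymous"))
        if is_hyper:
            met_muts.append(
                keys.substitution(
                    str(rng.choice(sorted(MISMATCH_REPAIR_PANEL.genes))),
                    effect="nonsynonymous",
                )
            )
            met_muts.append(
                keys.substitution(
                    str(rng.choice(sorted(POLYMERASE_PANEL.genes))),
                    effect="nonsynonymous",
                )
            )
        mutations.extend(_for_sample(pri_muts, pri))
        mutations.extend(_for_sample(met_muts, met))
        truth.mutation_counts[pri] = len(pri_muts)
        truth.mutation_counts[met] = len(met_muts)

        # --- SCNA profiles ------------------------------------------------
        met_loh_mean, met_loh_disp = (
            (config.loh_hypermutator_mean, config.loh_dispersion_hyper)
            if is_hyper
            else (config.loh_baseline_mean, config.loh_dispersion_baseline)
        )
        pri_cn, pri_loh = _base_profile(
            config, rng, n_bins, config.loh_baseline_mean,
            config.loh_dispersion_baseline,
        )
        if is_related:
            met_cn, met_loh = pri_cn.copy(), pri_loh.copy()
            noisy = np.flatnonzero(rng.random(n_bins) < config.scna_noise_rate)
            for j in noisy:
                if rng.random() < config.scna_event_rate:
                    met_cn[j] = int(rng.choice(_EVENT_STATES, p=_EVENT_WEIGHTS))
                else:
                    met_cn[j] = 2
                if met_cn[j] != 2:
                    met_loh[j] = False
            if is_hyper:
                target = _negbin(rng, met_loh_mean, met_loh_disp)
                _add_loh(rng, met_cn, met_loh, target - int(met_loh.sum()))
        else:
            met_cn, met_loh = _base_profile(
                config, rng, n_bins, met_loh_mean, met_loh_disp
            )
        segments.extend(_profile_segments(pri, pri_cn, pri_loh, bins))
        segments.extend(_profile_segments(met, met_cn, met_loh, bins))

    manifest = CohortManifest(patients=patients)
    return SimulatedCohort(
        config=config,
        mutations=mutations,
        segments=segments,
        manifest=manifest,
        truth=truth,
    )


@dataclass
class RecoveryReport:
    """Pipeline-vs-truth agreement over simulated replicates."""

    replicates: int
    n_pairs_total: int
    classification_accuracy: float
    adjacency_sensitivity: float
    adjacency_specificity: float
    hypermutator_accuracy: float
    fraction_related_called: float


def run_pipeline_on_cohort(cohort: SimulatedCohort):
    """Run every analysis stage on one simulated cohort.

    Returns (adjacency, concordances, clonality calls, hypermutation calls).
    """
    config = cohort.config
    matrix = build_cnv_matrix(
        cohort.segments,
        cohort.manifest,
        config.chrom_lengths,
        bin_size=config.bin_size,
    )
    dist = pairwise_distance(matrix, metric="euclidean")
    tree = hierarchical_cluster(dist, linkage="complete")
    adjacency = cohort_adjacency(tree, cohort.manifest)
    concordances = cohort_concordance(
        cohort.mutations, cohort.manifest, panel=config.driver_panel
    )
    calls = [
        classify_pair(adjacency.per_pair[c.patient_id], c) for c in concordances
    ]
    counts = {
        sid: 0 for sid in cohort.manifest.tumor_ids
    }
    for m in cohort.mutations:
        if m.sample_id in counts:
            counts[m.sample_id] += 1
    hyper_calls = annotate_panel_hits(
        call_hypermutated(counts, strategy="absolute"), cohort.mutations
    )
    return adjacency, concordances, calls, hyper_calls


def recovery_experiment(
    config: SimulationConfig, replicates: int = 20
) -> RecoveryReport:
    """Simulate ``replicates`` cohorts and score the pipeline against truth.

    Replicate *r* uses seed ``config.seed + r`` so the experiment is fully
    reproducible while replicates stay independent.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n_correct = n_pairs = 0
    adj_tp = adj_fn = adj_fp = adj_tn = 0
    hyper_correct = hyper_total = 0
    n_called_related = 0
    for r in range(replicates):
        cohort = simulate_cohort(replace(config, seed=config.seed + r))
        try:
            adjacency, _, calls, hyper_calls = run_pipeline_on_cohort(cohort)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed on replicate {r}") from exc
        for call in calls:
            truth_related = cohort.truth.related[call.patient_id]
            predicted_related = call.label == "related"
            n_correct += predicted_related == truth_related
            n_called_related += predicted_related
            n_pairs += 1
            adjacent = adjacency.per_pair[call.patient_id]
            if truth_related:
                adj_tp += adjacent
                adj_fn += not adjacent
            else:
                adj_fp += adjacent
                adj_tn += not adjacent
        for hc in hyper_calls:
            if hc.sample_id in cohort.truth.hypermutator:
                hyper_correct += (
                    hc.flagged == cohort.truth.hypermutator[hc.sample_id]
                )
                hyper_total += 1
    return RecoveryReport(
        replicates=replicates,
        n_pairs_total=n_pairs,
        classification_accuracy=n_correct / n_pairs,
        adjacency_sensitivity=adj_tp / max(adj_tp + adj_fn, 1),
        adjacency_specificity=adj_tn / max(adj_tn + adj_fp, 1),
        hypermutator_accuracy=hyper_correct / max(hyper_total, 1),
        fraction_related_called=n_called_related / n_pairs,
    )
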