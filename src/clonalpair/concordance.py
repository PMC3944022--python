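"""Shared-mutation statistics between paired tumor samples.

Two samples share a mutation when the calls agree on the full identity key
(chromosome, position, ref allele, alt allele).  The headline statistic per
pair is the shared percentage on the Jaccard scale,

    shared_pct = 100 * S / (n_a + n_b - S),

the shared calls as a fraction of the union of the two call sets.  Gene-level
statistics (driver concordance, per-gene mutation frequencies) consider only
non-silent calls (all effect classes except synonymous), while raw mutation
counts include all seven classes.

The module also classifies single-nucleotide substitutions into the six
pyrimidine-context classes (C>A, C>G, C>T, T>A, T>C, T>G), collapsing
purine-reference changes onto their reverse complement, for mutation-spectrum
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import (
    CohortManifest,
    MutationRecord,
    NON_SILENT_EFFECTS,
    group_by_sample,
)
from .panels import DRIVER_PANEL, GenePanel

MutationKey = tuple[str, int, str, str]


def mutation_keys(muts: Iterable[MutationRecord]) -> set[MutationKey]:
    """Distinct identity keys in a call list (within-sample duplicates collapse)."""
    return {m.key for m in muts}


def shared_mutations(
    muts_a: Iterable[MutationRecord], muts_b: Iterable[MutationRecord]
) -> set[MutationKey]:
    """Keys present in both samples."""
    return mutation_keys(muts_a) & mutation_keys(muts_b)


def shared_percentage(n_a: int, n_b: int, n_shared: int) -> float:
    """Jaccard shared percentage 100*S/(n_a + n_b - S); 0 when both empty."""
    if n_a < 0 or n_b < 0 or n_shared < 0:
        raise ValueError("counts must be non-negative")
    if n_shared > min(n_a, n_b):
        raise ValueError("shared count exceeds a sample's count")
    union = n_a + n_b - n_shared
    if union == 0:
        return 0.0
    return 100.0 * n_shared / union


def driver_concordance(
    muts_a: Iterable[MutationRecord],
    muts_b: Iterable[MutationRecord],
    panel: GenePanel = DRIVER_PANEL,
) -> tuple[set[str], set[str]]:
    """Split panel genes into shared vs discordant between two samples.

    A gene is *shared* when both samples carry a non-silent mutation with an
    identical key in that gene; *discordant* when at least one sample has a
    non-silent mutation in the gene but no key is shared.  Genes untouched in
    both samples appear in neither set.
    """
    keys_a: dict[str, set[MutationKey]] = {}
    keys_b: dict[str, set[MutationKey]] = {}
    for muts, table in ((muts_a, keys_a), (muts_b, keys_b)):
        for m in muts:
            if m.gene in panel and m.effect in NON_SILENT_EFFECTS:
                table.setdefault(m.gene, set()).add(m.key)
    shared, discordant = set(), set()
    for gene in set(keys_a) | set(keys_b):
        if keys_a.get(gene, set()) & keys_b.get(gene, set()):
            shared.add(gene)
        else:
            discordant.add(gene)
    return shared, discordant


@dataclass(frozen=True)
class PairConcordance:
    """Shared-mutation statistics for one primary/metastasis pair."""

    patient_id: str
    n_primary: int
    n_metastasis: int
    n_shared: int
    shared_driver_genes: frozenset[str]
    discordant_driver_genes: frozenset[str]

    @property
    def shared_pct(self) -> float:
        return shared_percentage(self.n_primary, self.n_metastasis, self.n_shared)


def pair_concordance(
    patient_id: str,
    muts_primary: Sequence[MutationRecord],
    muts_metastasis: Sequence[MutationRecord],
    panel: GenePanel = DRIVER_PANEL,
) -> PairConcordance:
    """Full concordance record for one pair (counts use all effect classes)."""
    keys_p = mutation_keys(muts_primary)
    keys_m = mutation_keys(muts_metastasis)
    shared, discordant = driver_concordance(muts_primary, muts_metastasis, panel)
    return PairConcordance(
        patient_id=patient_id,
        n_primary=len(keys_p),
        n_metastasis=len(keys_m),
        n_shared=len(keys_p & keys_m),
        shared_driver_genes=frozenset(shared),
        discordant_driver_genes=frozenset(discordant),
    )


def cohort_concordance(
    mutations: Iterable[MutationRecord],
    manifest: CohortManifest,
    panel: GenePanel = DRIVER_PANEL,
) -> list[PairConcordance]:
    by_sample = group_by_sample(mutations)
    return [
        pair_concordance(
            p.patient_id,
            by_sample.get(p.primary_sample_id, []),
            by_sample.get(p.metastasis_sample_id, []),
            panel,
        )
        for p in manifest
    ]


def gene_discordance_rate(
    mutations: Iterable[MutationRecord],
    manifest: CohortManifest,
    gene: str,
) -> tuple[int, int, float | None]:
    """Discordance rate of one gene across pairs.

    A pair is *informative* when at least one member carries a non-silent
    mutation in the gene; it is *discordant* when informative but no key in
    the gene is shared.  Returns (n_discordant, n_informative, rate); the
    rate is None (undefined) with zero informative pairs.
    """
    if not gene:
        raise ValueError("gene symbol must be non-empty")
    panel = GenePanel(name=gene, genes=frozenset({gene}))
    n_informative = n_discordant = 0
    by_sample = group_by_sample(mutations)
    for p in manifest:
        shared, discordant = driver_concordance(
            by_sample.get(p.primary_sample_id, []),
            by_sample.get(p.metastasis_sample_id, []),
            panel,
        )
        if shared or discordant:
            n_informative += 1
            if gene in discordant:
                n_discordant += 1
    rate = n_discordant / n_informative if n_informative else None
    return n_discordant, n_informative, rate


def gene_mutation_frequency(
    mutations: Iterable[MutationRecord],
    manifest: CohortManifest,
    gene: str,
    role: str,
) -> float:
    """Percent of samples of one role with a non-silent mutation in ``gene``.

    ``role`` is "primary" or "metastasis".  Not rounded; reports round to
    integer percent.
    """
    if role == "primary":
        sample_ids = manifest.primary_ids
    elif role == "metastasis":
        sample_ids = manifest.metastasis_ids
    else:
        raise ValueError(f"unknown role {role!r}; use 'primary' or 'metastasis'")
    if not sample_ids:
        raise ValueError("no samples of the requested role")
    mutated = {
        m.sample_id
        for m in mutations
        if m.gene == gene and m.effect in NON_SILENT_EFFECTS
    }
    n_hit = sum(1 for sid in sample_ids if sid in mutated)
    return 100.0 * n_hit / len(sample_ids)


SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def mutation_spectrum(muts: Iterable[MutationRecord]) -> dict[str, float]:
    """Proportion of substitutions in each pyrimidine-context class.

    Purine-reference changes are collapsed onto the reverse-complement
    pyrimidine class (e.g. G>T counts as C>A).  Indels are excluded.  With no
    substitutions at all the vector is all zeros.
    """
    counts = dict.fromkeys(SPECTRUM_CLASSES, 0)
    total = 0
    for m in muts:
        if not m.is_substitution:
            continue
        ref, alt = m.ref_allele, m.alt_allele
        if ref in "AG":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[f"{ref}>{alt}"] += 1
        total += 1
    if total == 0:
        return dict.fromkeys(SPECTRUM_CLASSES, 0.0)
    return {cls: n / total for cls, n in counts.items()}
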