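"""Final clonal-relatedness call per primary/metastasis pair.

Two independent evidence streams feed the call: whether the pair's profiles
are dendrogram siblings in SCNA clustering, and whether the pair shares a
driver-panel mutation at an identical genomic key.  In the reference cohort
the two agreed perfectly; in general they can disagree, so a third label is
used rather than forcing a binary call:

* ``related``             — siblings AND >=1 shared driver gene;
* ``distinct``            — not siblings AND no shared driver gene;
* ``discordant_evidence`` — the streams disagree.

The overall shared-mutation percentage is reported as evidence but does not
enter the rule; a pair called distinct while sharing a high fraction of
mutations gets a warning in its evidence trail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .concordance import PairConcordance

LABELS = ("related", "distinct", "discordant_evidence")

#: Shared-percentage above which a "distinct" call carries a warning.
HIGH_SHARING_WARNING_PCT = 20.0


@dataclass(frozen=True)
class ClonalityCall:
    patient_id: str
    adjacent: bool
    n_shared_drivers: int
    shared_pct: float
    label: str
    evidence: str


def classify_pair(adjacent: bool, concordance: PairConcordance) -> ClonalityCall:
    """Combine dendrogram adjacency and driver concordance into one label."""
    n_drivers = len(concordance.shared_driver_genes)
    pct = concordance.shared_pct
    if adjacent and n_drivers >= 1:
        label = "related"
    elif not adjacent and n_drivers == 0:
        label = "distinct"
    else:
        label = "discordant_evidence"
    drivers = ",".join(sorted(concordance.shared_driver_genes)) or "-"
    evidence = (
        f"dendrogram_sibling={adjacent}; shared_drivers={drivers}; "
        f"shared_pct={pct:.1f}"
    )
    if label == "distinct" and pct > HIGH_SHARING_WARNING_PCT:
        evidence += (
            f"; WARNING: called distinct but {pct:.1f}% of mutations are shared"
        )
    return ClonalityCall(
        patient_id=concordance.patient_id,
        adjacent=adjacent,
        n_shared_drivers=n_drivers,
        shared_pct=pct,
        label=label,
        evidence=evidence,
    )


@dataclass(frozen=True)
class CohortSummary:
    n_pairs: int
    n_related: int
    n_distinct: int
    n_discordant: int

    @property
    def fraction_related(self) -> float:
        return self.n_related / self.n_pairs


def summarize_cohort(calls: Sequence[ClonalityCall]) -> CohortSummary:
    """Partition counts over the three labels."""
    if not calls:
        raise ValueError("no calls to summarize")
    n_related = sum(c.label == "related" for c in calls)
    n_distinct = sum(c.label == "distinct" for c in calls)
    n_discordant = sum(c.label == "discordant_evidence" for c in calls)
    return CohortSummary(
        n_pairs=len(calls),
        n_related=n_related,
        n_distinct=n_distinct,
        n_discordant=n_discordant,
    )
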