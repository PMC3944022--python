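"""Reference cohort summary tables bundled with the package.

A published cohort of 15 colorectal carcinoma (CRC) / colorectal liver
metastasis (CLM) pairs is used throughout the test-suite and documentation as
a ground-truth fixture.  Two summary tables are bundled:

* per-sample SCNA category counts (one copy gain, one copy loss, high copy
  gain, homozygous loss, copy-neutral LOH), the published "total SCNA number"
  and the somatic mutation count;
* per-pair mutation counts with the published shared-point-mutation
  percentage and the hierarchical-clustering grouping call.

Only summary counts are bundled — the underlying arrays and sequence data are
not redistributed.  :func:`reference_segments` expands the category counts
into synthetic segment records (one segment per counted event) so that the
SCNA summary stage can be exercised end-to-end against the published totals.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import CohortManifest, PatientPair, SegmentRecord

# (patient, role, one_copy_gain, one_copy_loss, high_copy_gain,
#  homozygous_loss, loh, total_scna, somatic_mutations)
_SCNA_ROWS = [
    ("185", "CRC", 837, 271, 135, 92, 17, 1335, 101),
    ("185", "CLM", 829, 65, 0, 0, 1, 894, 34),
    ("250", "CRC", 2538, 1728, 110, 0, 12, 4376, 102),
    ("250", "CLM", 3334, 2611, 289, 132, 164, 6366, 890),
    ("262", "CRC", 1241, 875, 10, 0, 0, 2126, 95),
    ("262", "CLM", 1121, 1601, 72, 42, 146, 2836, 916),
    ("278", "CRC", 745, 378, 27, 139, 180, 1289, 72),
    ("278", "CLM", 1102, 533, 24, 132, 62, 1791, 65),
    ("353", "CRC", 289, 67, 9, 7, 0, 372, 66),
    ("353", "CLM", 1634, 1089, 0, 0, 0, 2723, 77),
    ("381", "CRC", 2339, 578, 2, 0, 0, 2919, 16),
    ("381", "CLM", 683, 392, 15, 0, 0, 1090, 84),
    ("413", "CRC", 389, 643, 4, 3, 0, 1039, 55),
    ("413", "CLM", 351, 211, 23, 0, 0, 585, 63),
    ("503", "CRC", 1493, 470, 19, 0, 1, 1982, 60),
    ("503", "CLM", 1103, 2187, 26, 0, 3, 3316, 65),
    ("509", "CRC", 1290, 508, 0, 0, 0, 1798, 71),
    ("509", "CLM", 240, 98, 14, 0, 6, 352, 98),
    ("523", "CRC", 792, 256, 16, 0, 1, 1064, 90),
    ("523", "CLM", 148, 84, 13, 0, 7, 245, 101),
    ("526", "CRC", 107, 107, 0, 0, 0, 214, 44),
    ("526", "CLM", 167, 281, 25, 43, 145, 516, 971),
    ("627", "CRC", 1863, 1878, 0, 1, 1, 3742, 44),
    ("627", "CLM", 811, 648, 0, 0, 0, 1459, 39),
    ("707", "CRC", 658, 1070, 0, 0, 0, 1728, 93),
    ("707", "CLM", 1276, 565, 235, 4, 80, 2080, 81),
    ("718", "CRC", 979, 330, 14, 0, 0, 1323, 58),
    ("718", "CLM", 1522, 327, 113, 45, 0, 2007, 69),
    ("721", "CRC", 538, 674, 0, 0, 20, 1212, 113),
    ("721", "CLM", 624, 307, 44, 62, 160, 1037, 819),
]

# (patient, grouped_in_clustering, crc_mutations, clm_mutations, shared_pct)
_PAIR_ROWS = [
    ("185", False, 101, 34, 0.0),
    ("250", False, 102, 890, 0.0),
    ("262", False, 95, 916, 0.2),
    ("353", False, 66, 77, 52.1),
    ("381", False, 16, 84, 3.1),
    ("526", False, 44, 971, 0.0),
    ("721", False, 113, 819, 0.1),
    ("278", True, 72, 65, 53.9),
    ("413", True, 55, 63, 43.9),
    ("503", True, 60, 65, 38.9),
    ("509", True, 71, 98, 30.0),
    ("523", True, 90, 101, 36.4),
    ("627", True, 44, 39, 45.6),
    ("707", True, 93, 81, 35.9),
    ("718", True, 58, 69, 46.0),
]

#: Metastasis samples reported as hypermutated (MSI phenotype) in the
#: reference cohort.
HYPERMUTATED_PATIENTS = ("250", "262", "526", "721")


def reference_scna_table() -> pd.DataFrame:
    """Per-sample SCNA category counts and mutation counts for the cohort."""
    return pd.DataFrame(
        _SCNA_ROWS,
        columns=[
            "patient",
            "role",
            "one_copy_gain",
            "one_copy_loss",
            "high_copy_gain",
            "homozygous_loss",
            "loh",
            "total_scna",
            "somatic_mutations",
        ],
    )


def reference_pair_table() -> pd.DataFrame:
    """Per-pair mutation counts, grouping calls, and shared percentages."""
    return pd.DataFrame(
        _PAIR_ROWS,
        columns=["patient", "grouped", "crc_mutations", "clm_mutations", "shared_pct"],
    )


def reference_manifest() -> CohortManifest:
    """Manifest for the 15 reference pairs, sample ids ``<patient>-CRC/-CLM``."""
    patients = sorted({row[0] for row in _SCNA_ROWS}, key=int)
    return CohortManifest(
        patients=[
            PatientPair(p, f"{p}-CRC", f"{p}-CLM", f"{p}-N") for p in patients
        ]
    )


# Category -> (copy_number, loh) used when expanding counts into segments.
_CATEGORY_STATES = {
    "one_copy_gain": (3, False),
    "one_copy_loss": (1, False),
    "high_copy_gain": (4, False),
    "homozygous_loss": (0, False),
    "loh": (2, True),
}

_SEGMENT_UNIT = 1000  # synthetic segment length in bp


def reference_segments(patients: list[str] | None = None) -> list[SegmentRecord]:
    """Synthetic segment records realising the cohort's category counts.

    One unit-length segment is emitted per counted event, laid end-to-end on
    a synthetic chromosome per sample; coordinates are bookkeeping only, but
    category counts (and hence SCNA summaries) match the published table
    exactly.
    """
    segments: list[SegmentRecord] = []
    for row in _SCNA_ROWS:
        patient, role = row[0], row[1]
        if patients is not None and patient not in patients:
            continue
        sample_id = f"{patient}-{role}"
        counts = dict(
            zip(
                ["one_copy_gain", "one_copy_loss", "high_copy_gain",
                 "homozygous_loss", "loh"],
                row[2:7],
            )
        )
        pos = 1
        for category, n in counts.items():
            cn, loh = _CATEGORY_STATES[category]
            for _ in range(n):
                segments.append(
                    SegmentRecord(
                        sample_id=sample_id,
                        chromosome="chrS",
                        start=pos,
                        end=pos + _SEGMENT_UNIT - 1,
                        copy_number=cn,
                        loh=loh,
                    )
                )
                pos += _SEGMENT_UNIT
    return segments


def reference_mutation_counts(role: str) -> dict[str, int]:
    """Published somatic mutation counts for one role ('CRC' or 'CLM')."""
    if role not in {"CRC", "CLM"}:
        raise ValueError(f"unknown role {role!r}")
    return {row[0]: row[8] for row in _SCNA_ROWS if row[1] == role}


def reference_loh_counts(role: str) -> dict[str, int]:
    """Published copy-neutral LOH counts for one role."""
    if role not in {"CRC", "CLM"}:
        raise ValueError(f"unknown role {role!r}")
    return {row[0]: row[6] for row in _SCNA_ROWS if row[1] == role}
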