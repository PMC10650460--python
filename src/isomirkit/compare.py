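"""Cross-sample and cross-species comparison of isomiR profiles.

Comparison is descriptive: shared labels, per-label counts and RPM, and
top-n rank agreement. Cross-species remapping decomposes one species'
canonical mature as if it were a read against the other species' reference,
which expresses relations such as "species A's canonical is species B's
Trim A isoform".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .caller import CallerParams, IsomiRCall, IsomiRProfile, decompose, rank_isoforms
from .reference import HairpinRef, MatureAnnotation


@dataclass
class ProfileComparison:
    left_sample: str
    right_sample: str
    mature_id: str
    n: int
    shared_labels: list[str]
    rank_agreement_at_n: float
    table: pd.DataFrame  # label, count_left, count_right, rpm_left, rpm_right


def compare_profiles(
    a: IsomiRProfile, b: IsomiRProfile, mature_id: str, n: int = 5
) -> ProfileComparison:
    """Deterministic descriptive comparison of two profiles for one miRNA.

    ``rank_agreement_at_n`` is |top-n(a) ∩ top-n(b)| / n over count-ranked
    labels; RPM (per-million-assigned) is reported alongside raw counts since
    library sizes differ between samples.
    """
    labels_a = set(a.labels(mature_id))
    labels_b = set(b.labels(mature_id))
    shared = sorted(labels_a & labels_b)

    def top_labels(profile: IsomiRProfile) -> set[str]:
        if mature_id not in {mid for (mid, _) in profile.entries}:
            return set()
        return {lab for lab, _ in rank_isoforms(profile, mature_id, n)}

    agreement = len(top_labels(a) & top_labels(b)) / n

    rpm_a, rpm_b = a.rpm, b.rpm
    rows = []
    for label in sorted(labels_a | labels_b):
        rows.append(
            {
                "label": label,
                "count_left": a.entries.get((mature_id, label), 0),
                "count_right": b.entries.get((mature_id, label), 0),
                "rpm_left": rpm_a.get((mature_id, label), 0.0),
                "rpm_right": rpm_b.get((mature_id, label), 0.0),
            }
        )
    table = pd.DataFrame(
        rows, columns=["label", "count_left", "count_right", "rpm_left", "rpm_right"]
    )
    return ProfileComparison(
        left_sample=a.sample_id,
        right_sample=b.sample_id,
        mature_id=mature_id,
        n=n,
        shared_labels=shared,
        rank_agreement_at_n=agreement,
        table=table,
    )


def relabel_against(
    mature_a: str,
    hairpin_b: HairpinRef,
    annot_b: MatureAnnotation,
    params: CallerParams = CallerParams(),
) -> Optional[IsomiRCall]:
    """Decompose one species' mature sequence against another species' reference.

    Returns the isomiR call expressing the cross-species relation (e.g. a
    mature equal to the other's minus its terminal base comes back "Trim
    <base>"; one with a non-templated terminal addition comes back "Plus
    <base>"), or None when no decomposition exists within limits
    (unrelated sequences).
    """
    return decompose(mature_a, hairpin_b, annot_b, params)
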