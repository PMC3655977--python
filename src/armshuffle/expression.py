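"""Gonad-specific expression calls from probe-level present/absent data.

A gene is ovary-specific when at least one of its probes is "present" in
more than two of four ovary hybridizations while none of its probes is
present in more than two of four testis hybridizations; testis-specific is
the mirror image.  The two definitions are mutually exclusive: a probe
with >2 presents in both gonads blocks both.  Everything else is untagged.
The tags proxy germ-line accessibility of each gene.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

from .genome_model import ProbeCalls


def classify_gene(calls: Sequence[ProbeCalls]) -> str:
    """Classify one gene from all of its probes' calls."""
    if not calls:
        raise ValueError("classify_gene: gene has zero probes")
    any_ovary = any(sum(pc.ovary_present) > 2 for pc in calls)
    any_testis = any(sum(pc.testis_present) > 2 for pc in calls)
    all_ovary_low = all(sum(pc.ovary_present) <= 2 for pc in calls)
    all_testis_low = all(sum(pc.testis_present) <= 2 for pc in calls)
    if any_ovary and all_testis_low:
        return "ovary_specific"
    if any_testis and all_ovary_low:
        return "testis_specific"
    return "untagged"


def classify_all(
    calls: Iterable[ProbeCalls],
    gene_arms: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], dict[str, Counter] | None]:
    """Classify every gene; optionally tally tag counts per chromosome arm.

    Returns (gene_id -> tag, arm -> Counter of tags).  The per-arm counts
    (available when ``gene_arms`` maps gene ids to arm names) are what the
    arm-stratified permutation nulls preserve.
    """
    by_gene: dict[str, list[ProbeCalls]] = {}
    for pc in calls:
        by_gene.setdefault(pc.gene_id, []).append(pc)
    tags = {g: classify_gene(pcs) for g, pcs in by_gene.items()}
    if gene_arms is None:
        return tags, None
    per_arm: dict[str, Counter] = {}
    for g, tag in tags.items():
        arm = gene_arms.get(g)
        if arm is not None:
            per_arm.setdefault(arm, Counter())[tag] += 1
    return tags, per_arm
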