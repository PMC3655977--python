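"""End-to-end orchestration: all three analyses for every definition.

``run_all`` mirrors the full study: derive Lam status for the OLs, run the
CNP relocation test for all/deletion/duplication event classes, the
breakpoint-ratio tag-permutation test, and the synteny-class analyses
(trend test + per-class ratio permutation tests), for each requested
stability definition.  Every (definition x test) cell of the report is
present, either with a result or with an explicit skip reason.  Raw
empirical p-values are reported with no multiple-testing correction across
definitions or tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .genome_model import (
    CNP,
    ChromosomeArm,
    GeneRecord,
    OLRegion,
    PermutationResult,
    TrendTestResult,
    derive_lam_status,
    write_results,
)
from .breakpoints import breakpoint_permutation_test
from .cnp_enrichment import KIND_FILTERS, cnp_enrichment_test, count_cnps_per_ol
from .synteny import (
    build_class_tag_table,
    class_ratio_permutation_test,
    trend_chi_square,
)

logger = logging.getLogger("armshuffle")


@dataclass
class Report:
    """Consolidated run output: results keyed by (definition, test) labels."""

    seed: int
    replicates: int
    version: str = __version__
    permutation: dict[str, PermutationResult] = field(default_factory=dict)
    trend: dict[str, TrendTestResult] = field(default_factory=dict)
    tables: dict[str, list[list[int]]] = field(default_factory=dict)
    fractions_within_ol: dict[str, float] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows: list[tuple[str, str]] = [
            ("version", self.version),
            ("seed", str(self.seed)),
            ("replicates", str(self.replicates)),
        ]
        for key, res in sorted(self.permutation.items()):
            rows += [
                (f"{key}.observed", repr(res.observed)),
                (f"{key}.p_upper", repr(res.p_upper)),
                (f"{key}.p_lower", repr(res.p_lower)),
                (f"{key}.n_invalid", str(res.n_invalid)),
            ]
            write_results(res, outdir / key.replace("/", "_"))
        for key, tr in sorted(self.trend.items()):
            rows += [
                (f"{key}.chi_square", repr(tr.chi_square)),
                (f"{key}.df", str(tr.degrees_of_freedom)),
                (f"{key}.p_value", repr(tr.p_value)),
            ]
        for key, tab in sorted(self.tables.items()):
            rows.append((f"{key}.counts", ";".join(",".join(map(str, r)) for r in tab)))
        for key, frac in sorted(self.fractions_within_ol.items()):
            rows.append((f"{key}.fraction_within_ol", repr(frac)))
        for key, reason in sorted(self.skipped.items()):
            rows.append((f"{key}.skipped", reason))
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(
            outdir / "summary.tsv", sep="\t", index=False
        )


def run_all(
    *,
    genes: Sequence[GeneRecord],
    ols: Sequence[OLRegion] | None = None,
    cnps: Sequence[CNP] | None = None,
    arms: Sequence[ChromosomeArm] | None = None,
    lamin_gene_ids: set[str] | None = None,
    definitions: Sequence[str] = ("OLC", "GO", "GOO"),
    replicates: int = 10_000,
    seed: int = 0,
) -> Report:
    """Run every analysis for every definition; never silently drop a cell."""
    report = Report(seed=seed, replicates=replicates)
    ols_lam = None
    if ols is not None and lamin_gene_ids is not None:
        ols_lam, n_lam, n_nonlam = derive_lam_status(list(ols), lamin_gene_ids)
        logger.info("Lam status: %d Lam OLs, %d non-Lam OLs", n_lam, n_nonlam)

    for d in definitions:
        # Stage 1: CNP enrichment per event class
        for kind in KIND_FILTERS:
            key = f"{d}/cnp_{kind}"
            if ols_lam is None or cnps is None or arms is None:
                report.skipped[key] = "no OL/CNP/arm tables provided"
                continue
            try:
                report.permutation[key] = cnp_enrichment_test(
                    list(cnps), ols_lam, list(arms), kind=kind,
                    replicates=replicates, seed=seed,
                )
                counts = count_cnps_per_ol(list(cnps), ols_lam, kind=kind)
                report.fractions_within_ol[key] = counts.fraction_within_ol
            except (ValueError, ArithmeticError) as exc:
                report.skipped[key] = f"stage-1 ({kind}): {exc}"

        # Stage 2: breakpoint ratio
        key = f"{d}/breakpoints"
        try:
            for sub, res in breakpoint_permutation_test(
                list(genes), d, replicates=replicates, seed=seed
            ).items():
                report.permutation[f"{key}_{sub}"] = res
        except (ValueError, KeyError, ArithmeticError) as exc:
            report.skipped[key] = f"stage-2: {exc}"

        # Stage 3: class table, trend test, per-class ratios
        key = f"{d}/synteny"
        try:
            table = build_class_tag_table(list(genes), d)
            report.tables[key] = table.counts.tolist()
            report.trend[key] = trend_chi_square(table)
        except (ValueError, KeyError, ArithmeticError) as exc:
            report.skipped[f"{key}_trend"] = f"stage-3 trend: {exc}"
        try:
            for cls, res in class_ratio_permutation_test(
                list(genes), d, replicates=replicates, seed=seed
            ).items():
                report.permutation[f"{key}_{cls}"] = res
        except (ValueError, KeyError, ArithmeticError) as exc:
            report.skipped[f"{key}_ratio"] = f"stage-3 ratios: {exc}"

    return report
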