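"""Domain types and table I/O for arm-stratified gene-order analyses.

Coordinate convention: input/output TSV tables are 1-based inclusive
(FlyBase style); everything in memory is 0-based half-open, so interval
length is always ``end - start``.  Readers convert on the way in, writers
convert back, and the round trip is the identity on well-formed tables.

The central objects are orthologous landmarks (OLs) — chromosome segments
whose internal gene arrangement is conserved across a genus, under one of
three stringency definitions (OLC: overall local contiguity; GO: gene
order; GOO: gene order and orientation) — together with copy-number
polymorphisms (CNPs), OL genes annotated with rearrangement-breakpoint
counts per flank, and probe-level gonadal expression calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("armshuffle")

DEFINITIONS = ("OLC", "GO", "GOO")
CNP_KINDS = ("deletion", "duplication")
TAGS = ("ovary_specific", "testis_specific", "untagged")


class UndefinedStatisticError(ArithmeticError):
    """A ratio statistic has a zero denominator and is undefined."""


@dataclass(frozen=True)
class ChromosomeArm:
    """A chromosome arm: the stratification unit of every null model."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"arm {self.name!r}: length must be > 0")


@dataclass
class OLRegion:
    """A gene-order-stable interval (orthologous landmark)."""

    id: str
    arm: str
    start: int
    end: int
    definition: str
    gene_ids: tuple[str, ...]
    is_lam: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"OL {self.id!r}: require 0 <= start < end")
        if self.definition not in DEFINITIONS:
            raise ValueError(f"OL {self.id!r}: unknown definition {self.definition!r}")
        if not self.gene_ids:
            raise ValueError(f"OL {self.id!r}: OLs are defined by gene content; empty gene list")

    @property
    def length(self) -> int:
        """Interval length A in bp (end - start)."""
        return self.end - self.start


@dataclass
class CNP:
    """A copy-number polymorphism: a segregating deletion or duplication."""

    id: str
    arm: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"CNP {self.id!r}: require 0 <= start < end")
        if self.kind not in CNP_KINDS:
            raise ValueError(f"CNP {self.id!r}: kind must be one of {CNP_KINDS}, got {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneRecord:
    """An OL gene with per-definition breakpoint/flank annotation.

    ``left_breakpoints``/``right_breakpoints`` count gene-order-disrupting
    rearrangement breakpoints on each flank, keyed by stability definition.
    ``left_changed``/``right_changed`` record whether the flanking gene
    changed at least once (copied from the input annotation, never
    inferred).  Nesting links are mutually consistent by construction:
    ``hosts`` is derived from ``nested_in`` at read time.
    """

    id: str
    arm: str
    start: int
    end: int
    left_breakpoints: dict[str, int] = field(default_factory=dict)
    right_breakpoints: dict[str, int] = field(default_factory=dict)
    left_changed: dict[str, bool] = field(default_factory=dict)
    right_changed: dict[str, bool] = field(default_factory=dict)
    nested_in: str | None = None
    hosts: tuple[str, ...] = ()
    tag: str = "untagged"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.id!r}: require 0 <= start < end")
        if self.nested_in == self.id:
            raise ValueError(f"gene {self.id!r} cannot be nested in itself")
        for d, v in {**self.left_breakpoints, **self.right_breakpoints}.items():
            if v < 0:
                raise ValueError(f"gene {self.id!r}: negative breakpoint count for {d}")
        if self.tag not in TAGS:
            raise ValueError(f"gene {self.id!r}: unknown tag {self.tag!r}")

    def breakpoints_total(self, definition: str) -> int:
        """Breakpoints per gene: left + right flank counts for ``definition``."""
        try:
            return self.left_breakpoints[definition] + self.right_breakpoints[definition]
        except KeyError:
            raise KeyError(
                f"gene {self.id!r}: no breakpoint annotation for definition {definition!r}"
            ) from None


@dataclass
class ProbeCalls:
    """Present/absent calls for one probe: 4 hybridizations per gonad."""

    gene_id: str
    probe_id: str
    ovary_present: tuple[bool, bool, bool, bool]
    testis_present: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        if len(self.ovary_present) != 4 or len(self.testis_present) != 4:
            raise ValueError(
                f"probe {self.probe_id!r}: exactly 4 calls per tissue required"
            )


@dataclass
class PermutationResult:
    """Observed statistic plus its Monte Carlo null distribution.

    ``p_upper``/``p_lower`` are the fractions of *valid* replicates with
    null statistic >= / <= the observed value (ties counted in both), so
    ``p_upper + p_lower >= 1`` whenever no replicate is invalid.
    """

    label: str
    observed: float
    null_values: np.ndarray
    p_upper: float
    p_lower: float
    replicates: int
    n_invalid: int = 0
    seed: int | None = None

    @property
    def n_valid(self) -> int:
        return self.replicates - self.n_invalid


@dataclass(frozen=True)
class TrendTestResult:
    """Cochran-Armitage chi-square test for trend on a 3x2 table (df = 1)."""

    chi_square: float
    degrees_of_freedom: int
    p_value: float


# ---------------------------------------------------------------------------
# Table readers (1-based inclusive files -> 0-based half-open objects)
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _to_int(value: str, *, path: Path | str, row: int, col: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValueError(f"{path} row {row}: column {col!r} is not an integer: {value!r}") from None


def _check_unique(ids: Iterable[str], what: str, path: str | Path) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"{path}: duplicate {what} id {i!r}")
        seen.add(i)


def _arm_lengths(arms: Sequence[ChromosomeArm] | None) -> dict[str, int] | None:
    if arms is None:
        return None
    lengths = {a.name: a.length for a in arms}
    if len(lengths) != len(arms):
        raise ValueError("arm names must be unique within a genome")
    return lengths


def read_arm_table(path: str | Path) -> list[ChromosomeArm]:
    df = _read_tsv(path, ["arm", "length"])
    arms = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        arms.append(ChromosomeArm(rec.arm, _to_int(rec.length, path=path, row=row, col="length")))
    _arm_lengths(arms)  # uniqueness check
    return arms


def _validate_interval(
    arm: str, start: int, end: int, lengths: dict[str, int] | None,
    *, path: str | Path, row: int,
) -> None:
    if lengths is not None:
        if arm not in lengths:
            raise ValueError(f"{path} row {row}: unknown arm {arm!r}")
        if end > lengths[arm]:
            raise ValueError(f"{path} row {row}: interval end {end} exceeds arm {arm!r} length")
    if start >= end:
        raise ValueError(f"{path} row {row}: start >= end after coordinate conversion")


def read_ol_table(
    path: str | Path,
    definition: str,
    arms: Sequence[ChromosomeArm] | None = None,
) -> list[OLRegion]:
    """Read an OL table (columns id, arm, start, end, gene_ids; ';'-lists).

    Coordinates in the file are 1-based inclusive; returned OLs use the
    internal 0-based half-open convention with ``is_lam`` initialised False.
    Overlapping OLs on one arm violate the definition and raise an error.
    """
    if definition not in DEFINITIONS:
        raise ValueError(f"unknown stability definition {definition!r}")
    df = _read_tsv(path, ["id", "arm", "start", "end", "gene_ids"])
    _check_unique(df["id"], "OL", path)
    lengths = _arm_lengths(arms)
    ols: list[OLRegion] = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        start = _to_int(rec.start, path=path, row=row, col="start") - 1
        end = _to_int(rec.end, path=path, row=row, col="end")
        _validate_interval(rec.arm, start, end, lengths, path=path, row=row)
        gene_ids = tuple(g for g in rec.gene_ids.split(";") if g)
        if not gene_ids:
            raise ValueError(f"{path} row {row}: OL {rec.id!r} has no genes")
        ols.append(OLRegion(rec.id, rec.arm, start, end, definition, gene_ids))
    _assert_no_overlap(ols)
    return ols


def _assert_no_overlap(ols: Sequence[OLRegion]) -> None:
    by_arm: dict[str, list[OLRegion]] = {}
    for o in ols:
        by_arm.setdefault(o.arm, []).append(o)
    for arm, group in by_arm.items():
        group = sorted(group, key=lambda o: o.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"OLs {a.id!r} and {b.id!r} overlap on arm {arm!r}: "
                    "within one stability definition OLs must be disjoint"
                )


def read_cnp_table(
    path: str | Path, arms: Sequence[ChromosomeArm] | None = None
) -> list[CNP]:
    df = _read_tsv(path, ["id", "arm", "start", "end", "kind"])
    _check_unique(df["id"], "CNP", path)
    lengths = _arm_lengths(arms)
    cnps = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        start = _to_int(rec.start, path=path, row=row, col="start") - 1
        end = _to_int(rec.end, path=path, row=row, col="end")
        _validate_interval(rec.arm, start, end, lengths, path=path, row=row)
        if rec.kind not in CNP_KINDS:
            raise ValueError(f"{path} row {row}: CNP kind must be one of {CNP_KINDS}")
        cnps.append(CNP(rec.id, rec.arm, start, end, rec.kind))
    return cnps


def read_gene_table(
    path: str | Path,
    definitions: Sequence[str] = DEFINITIONS,
    arms: Sequence[ChromosomeArm] | None = None,
) -> list[GeneRecord]:
    """Read a gene table with per-definition breakpoint/flank columns.

    Expected columns: id, arm, start, end, nested_in ('-' for none), and for
    each definition D in ``definitions`` present in the header:
    left_bp_D, right_bp_D, left_changed_D, right_changed_D.  ``hosts`` links
    are derived from ``nested_in`` so the nesting relation is consistent.
    """
    df = _read_tsv(path, ["id", "arm", "start", "end", "nested_in"])
    _check_unique(df["id"], "gene", path)
    lengths = _arm_lengths(arms)
    present_defs = [d for d in definitions if f"left_bp_{d}" in df.columns]
    genes: list[GeneRecord] = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        start = _to_int(rec.start, path=path, row=row, col="start") - 1
        end = _to_int(rec.end, path=path, row=row, col="end")
        _validate_interval(rec.arm, start, end, lengths, path=path, row=row)
        left_bp, right_bp, left_ch, right_ch = {}, {}, {}, {}
        for d in present_defs:
            left_bp[d] = _to_int(getattr(rec, f"left_bp_{d}"), path=path, row=row, col=f"left_bp_{d}")
            right_bp[d] = _to_int(getattr(rec, f"right_bp_{d}"), path=path, row=row, col=f"right_bp_{d}")
            left_ch[d] = getattr(rec, f"left_changed_{d}") == "1"
            right_ch[d] = getattr(rec, f"right_changed_{d}") == "1"
        nested_in = rec.nested_in if rec.nested_in not in ("", "-") else None
        genes.append(
            GeneRecord(
                rec.id, rec.arm, start, end,
                left_breakpoints=left_bp, right_breakpoints=right_bp,
                left_changed=left_ch, right_changed=right_ch,
                nested_in=nested_in,
            )
        )
    link_nesting(genes)
    return genes


def link_nesting(genes: Sequence[GeneRecord]) -> None:
    """Fill ``hosts`` from ``nested_in`` links; error on dangling references."""
    by_id = {g.id: g for g in genes}
    hosts: dict[str, list[str]] = {}
    for g in genes:
        if g.nested_in is not None:
            if g.nested_in not in by_id:
                raise ValueError(f"gene {g.id!r}: nested_in points to absent gene {g.nested_in!r}")
            hosts.setdefault(g.nested_in, []).append(g.id)
    for g in genes:
        g.hosts = tuple(hosts.get(g.id, ()))


def read_lamin_targets(path: str | Path) -> set[str]:
    """Read a one-column table of Lamin target gene identifiers."""
    df = _read_tsv(path, ["gene_id"])
    return set(df["gene_id"])


def read_tag_table(path: str | Path) -> dict[str, str]:
    df = _read_tsv(path, ["gene_id", "tag"])
    _check_unique(df["gene_id"], "gene", path)
    tags = {}
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        if rec.tag not in TAGS:
            raise ValueError(f"{path} row {row}: unknown tag {rec.tag!r}")
        tags[rec.gene_id] = rec.tag
    return tags


def read_probe_calls(path: str | Path) -> list[ProbeCalls]:
    """Read long-format probe calls: gene_id, probe_id, tissue, hyb_index, present."""
    df = _read_tsv(path, ["gene_id", "probe_id", "tissue", "hyb_index", "present"])
    probes: dict[tuple[str, str], dict[str, dict[int, bool]]] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        if rec.tissue not in ("ovary", "testis"):
            raise ValueError(f"{path} row {row}: tissue must be 'ovary' or 'testis'")
        idx = _to_int(rec.hyb_index, path=path, row=row, col="hyb_index")
        if not 1 <= idx <= 4:
            raise ValueError(f"{path} row {row}: hyb_index must be in 1..4")
        if rec.present not in ("0", "1"):
            raise ValueError(f"{path} row {row}: present must be 0 or 1")
        slot = probes.setdefault((rec.gene_id, rec.probe_id), {"ovary": {}, "testis": {}})
        if idx in slot[rec.tissue]:
            raise ValueError(f"{path} row {row}: duplicate call for probe {rec.probe_id!r}")
        slot[rec.tissue][idx] = rec.present == "1"
    out = []
    for (gene_id, probe_id), calls in probes.items():
        for tissue in ("ovary", "testis"):
            if sorted(calls[tissue]) != [1, 2, 3, 4]:
                raise ValueError(
                    f"{path}: probe {probe_id!r} has {len(calls[tissue])} {tissue} calls, need 4"
                )
        out.append(
            ProbeCalls(
                gene_id, probe_id,
                tuple(calls["ovary"][i] for i in (1, 2, 3, 4)),
                tuple(calls["testis"][i] for i in (1, 2, 3, 4)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Writers (inverse conversion: internal 0-based half-open -> 1-based inclusive)
# ---------------------------------------------------------------------------

def write_arm_table(arms: Sequence[ChromosomeArm], path: str | Path) -> None:
    pd.DataFrame({"arm": [a.name for a in arms], "length": [a.length for a in arms]}).to_csv(
        path, sep="\t", index=False
    )


def write_ol_table(ols: Sequence[OLRegion], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [o.id for o in ols],
            "arm": [o.arm for o in ols],
            "start": [o.start + 1 for o in ols],
            "end": [o.end for o in ols],
            "gene_ids": [";".join(o.gene_ids) for o in ols],
        }
    ).to_csv(path, sep="\t", index=False)


def write_cnp_table(cnps: Sequence[CNP], path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [c.id for c in cnps],
            "arm": [c.arm for c in cnps],
            "start": [c.start + 1 for c in cnps],
            "end": [c.end for c in cnps],
            "kind": [c.kind for c in cnps],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_table(
    genes: Sequence[GeneRecord], path: str | Path, definitions: Sequence[str] = DEFINITIONS
) -> None:
    cols: dict[str, list] = {
        "id": [g.id for g in genes],
        "arm": [g.arm for g in genes],
        "start": [g.start + 1 for g in genes],
        "end": [g.end for g in genes],
        "nested_in": [g.nested_in or "-" for g in genes],
    }
    present = [d for d in definitions if all(d in g.left_breakpoints for g in genes)] if genes else list(definitions)
    for d in present:
        cols[f"left_bp_{d}"] = [g.left_breakpoints[d] for g in genes]
        cols[f"right_bp_{d}"] = [g.right_breakpoints[d] for g in genes]
        cols[f"left_changed_{d}"] = [int(g.left_changed[d]) for g in genes]
        cols[f"right_changed_{d}"] = [int(g.right_changed[d]) for g in genes]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_tag_table(tags: Mapping[str, str], path: str | Path) -> None:
    items = sorted(tags.items())
    pd.DataFrame({"gene_id": [k for k, _ in items], "tag": [v for _, v in items]}).to_csv(
        path, sep="\t", index=False
    )


def write_probe_calls(calls: Sequence[ProbeCalls], path: str | Path) -> None:
    rows = []
    for pc in calls:
        for tissue, vals in (("ovary", pc.ovary_present), ("testis", pc.testis_present)):
            for i, v in enumerate(vals, start=1):
                rows.append((pc.gene_id, pc.probe_id, tissue, i, int(v)))
    pd.DataFrame(rows, columns=["gene_id", "probe_id", "tissue", "hyb_index", "present"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(result: PermutationResult, path_prefix: str | Path) -> None:
    """Write a PermutationResult as ``<prefix>.summary.tsv`` + ``<prefix>.nulls.tsv``."""
    prefix = Path(path_prefix)
    summary = [
        ("label", result.label),
        ("observed", repr(float(result.observed))),
        ("replicates", str(result.replicates)),
        ("n_invalid", str(result.n_invalid)),
        ("p_upper", repr(float(result.p_upper))),
        ("p_lower", repr(float(result.p_lower))),
        ("seed", "" if result.seed is None else str(result.seed)),
    ]
    pd.DataFrame(summary, columns=["key", "value"]).to_csv(
        prefix.with_suffix(".summary.tsv"), sep="\t", index=False
    )
    pd.DataFrame({"null_value": [repr(float(v)) for v in np.asarray(result.null_values)]}).to_csv(
        prefix.with_suffix(".nulls.tsv"), sep="\t", index=False
    )


def read_results(path_prefix: str | Path) -> PermutationResult:
    prefix = Path(path_prefix)
    summary = dict(
        pd.read_csv(prefix.with_suffix(".summary.tsv"), sep="\t", dtype=str, keep_default_na=False)
        .itertuples(index=False, name=None)
    )
    nulls_df = pd.read_csv(prefix.with_suffix(".nulls.tsv"), sep="\t")
    nulls = nulls_df["null_value"].to_numpy(dtype=float) if len(nulls_df) else np.array([])
    return PermutationResult(
        label=summary["label"],
        observed=float(summary["observed"]),
        null_values=nulls,
        p_upper=float(summary["p_upper"]),
        p_lower=float(summary["p_lower"]),
        replicates=int(summary["replicates"]),
        n_invalid=int(summary["n_invalid"]),
        seed=None if summary.get("seed", "") == "" else int(summary["seed"]),
    )


# ---------------------------------------------------------------------------
# Lam status
# ---------------------------------------------------------------------------

def derive_lam_status(
    ols: Sequence[OLRegion], lamin_gene_ids: set[str]
) -> tuple[list[OLRegion], int, int]:
    """Mark each OL as Lam iff it contains >= 1 Lamin target gene.

    Lam OLs proxy the peripherome: the genome fraction interacting with the
    nuclear lamina in somatic cells.  Returns new OLRegion objects plus the
    (L, nL) counts of Lam and non-Lam OLs.  Lamin ids matching no OL gene
    are logged as a warning, not an error (the Lamin set covers the whole
    genome, not only OL genes).
    """
    covered: set[str] = set()
    out = []
    for o in ols:
        hit = bool(set(o.gene_ids) & lamin_gene_ids)
        covered |= set(o.gene_ids) & lamin_gene_ids
        out.append(replace(o, is_lam=hit))
    orphans = lamin_gene_ids - covered
    if orphans:
        logger.warning("%d Lamin target ids match no OL gene", len(orphans))
    n_lam = sum(o.is_lam for o in out)
    return out, n_lam, len(out) - n_lam
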