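"""Synthetic input bundles with the structure the three analyses assume.

The generator emulates, at a reduced scale, the inputs of the real study:
a genome of several chromosome arms carrying non-overlapping orthologous
landmarks (OLs) of log-normal length — Lam OLs drawn with a larger median,
since lamina-associated domains tend to be long — tiled with genes; gonadal
expression tags; per-flank rearrangement-breakpoint counts; probe-level
present/absent calls that reproduce the tags through the expression
classifier; and CNPs scattered arm-uniformly.

Three effect-size dials define planted signal (all 1.0 = null regime):

* ``lam_deletion_multiplier`` (lambda): deletions are placed by rejection
  sampling so that positions hitting a Lam OL are accepted at lambda times
  the uniform rate;
* ``testis_breakpoint_multiplier`` (theta): flank breakpoint counts are
  Poisson with rate theta * mu for testis-specific genes, mu otherwise;
* ``class_tag_bias`` (beta): tags of bisyntenic genes are re-drawn with
  the testis probability odds multiplied by beta.

Flank-change flags are coupled to breakpoint counts (a flank with > 0
breakpoints is always "changed"); extra changes occur at
``flank_change_rate`` so the synteny classes are populated even where no
breakpoint was drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import (
    CNP,
    ChromosomeArm,
    DEFINITIONS,
    GeneRecord,
    OLRegion,
    ProbeCalls,
    derive_lam_status,
    link_nesting,
    write_arm_table,
    write_cnp_table,
    write_gene_table,
    write_ol_table,
    write_probe_calls,
    write_tag_table,
)

_ARM_NAMES = ("2L", "2R", "3L", "3R", "X", "A6", "A7", "A8", "A9", "A10")


@dataclass
class SyntheticConfig:
    """Generator contract: sizes, distributions, effect dials, and seed."""

    n_arms: int = 5
    arm_length: int = 2_000_000
    n_ols_per_arm: int = 30
    lam_fraction: float = 0.25
    ol_length_mu: float = log(20_000)
    ol_length_sigma: float = 0.6
    lam_ol_length_mu: float = log(40_000)
    genes_per_ol: tuple[int, int] = (3, 8)
    tag_ovary: float = 0.10
    tag_testis: float = 0.20
    n_cnps: int = 400
    deletion_fraction: float = 0.5
    cnp_length_mu: float = log(2_000)
    cnp_length_sigma: float = 0.8
    lam_deletion_multiplier: float = 1.0
    testis_breakpoint_multiplier: float = 1.0
    baseline_breakpoint_rate: float = 0.5
    class_tag_bias: float = 1.0
    flank_change_rate: float = 0.10
    nested_fraction: float = 0.05
    probe_noise: float = 0.01
    definitions: tuple[str, ...] = DEFINITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lam_fraction", "tag_ovary", "tag_testis", "deletion_fraction",
                     "flank_change_rate", "nested_fraction", "probe_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tag_ovary + self.tag_testis > 1.0:
            raise ValueError("tag fractions must sum to <= 1")
        for name in ("lam_deletion_multiplier", "testis_breakpoint_multiplier",
                     "class_tag_bias"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_arms < 1 or self.n_arms > len(_ARM_NAMES):
            raise ValueError(f"n_arms must be in 1..{len(_ARM_NAMES)}")
        if self.genes_per_ol[0] < 1 or self.genes_per_ol[0] > self.genes_per_ol[1]:
            raise ValueError("genes_per_ol must be a (low, high) range with low >= 1")
        for d in self.definitions:
            if d not in DEFINITIONS:
                raise ValueError(f"unknown definition {d!r}")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SyntheticConfig":
        """Reduced-size preset for repeated calibration/power experiments."""
        base = dict(
            n_arms=3,
            arm_length=800_000,
            n_ols_per_arm=12,
            lam_fraction=0.30,
            ol_length_mu=log(12_000),
            ol_length_sigma=0.5,
            lam_ol_length_mu=log(24_000),
            genes_per_ol=(3, 6),
            n_cnps=200,
            cnp_length_mu=log(1_500),
            cnp_length_sigma=0.7,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class Bundle:
    """A complete synthetic input set, writable as the standard TSV tables."""

    arms: list[ChromosomeArm]
    ols: list[OLRegion]
    genes: list[GeneRecord]
    cnps: list[CNP]
    lamin_gene_ids: set[str]
    probe_calls: list[ProbeCalls]
    config: SyntheticConfig | None = None

    @property
    def tags(self) -> dict[str, str]:
        return {g.id: g.tag for g in self.genes}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_arm_table(self.arms, outdir / "arms.tsv")
        write_ol_table(self.ols, outdir / "ols.tsv")
        write_gene_table(self.genes, outdir / "genes.tsv")
        write_cnp_table(self.cnps, outdir / "cnps.tsv")
        write_tag_table(self.tags, outdir / "tags.tsv")
        write_probe_calls(self.probe_calls, outdir / "probes.tsv")
        import pandas as pd

        pd.DataFrame({"gene_id": sorted(self.lamin_gene_ids)}).to_csv(
            outdir / "lamin.tsv", sep="\t", index=False
        )


def _draw_tags(rng: np.random.Generator, n: int, p_ovary: float, p_testis: float) -> np.ndarray:
    u = rng.random(n)
    tags = np.zeros(n, dtype=np.int8)  # 0 untag, 1 ovary, 2 testis
    tags[u < p_ovary] = 1
    tags[(u >= p_ovary) & (u < p_ovary + p_testis)] = 2
    return tags


_TAG_NAMES = {0: "untagged", 1: "ovary_specific", 2: "testis_specific"}

_BASE_CALLS = {
    "ovary_specific": ((1, 1, 1, 1), (0, 0, 0, 0)),
    "testis_specific": ((0, 0, 0, 0), (1, 1, 1, 1)),
    # untagged genes are emitted as broadly expressed (present in both
    # gonads): >2 presents on each side blocks both specificity rules and
    # is robust to single flipped calls
    "untagged": ((1, 1, 1, 1), (1, 1, 1, 1)),
}


def _probe_for(gene_id: str, tag: str, noise: float, rng: np.random.Generator) -> ProbeCalls:
    ov, te = _BASE_CALLS[tag]
    flip = rng.random(8) < noise
    ov = tuple(bool(v) ^ bool(f) for v, f in zip(ov, flip[:4]))
    te = tuple(bool(v) ^ bool(f) for v, f in zip(te, flip[4:]))
    return ProbeCalls(gene_id, f"{gene_id}_p1", ov, te)


def simulate_bundle(config: SyntheticConfig) -> Bundle:
    """Generate a full input bundle under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    arms = [ChromosomeArm(_ARM_NAMES[i], config.arm_length) for i in range(config.n_arms)]

    ols: list[OLRegion] = []
    genes: list[GeneRecord] = []
    lamin: set[str] = set()
    intended_lam: list[bool] = []

    for arm in arms:
        n = config.n_ols_per_arm
        is_lam = rng.random(n) < config.lam_fraction
        mu = np.where(is_lam, config.lam_ol_length_mu, config.ol_length_mu)
        lengths = np.maximum(
            rng.lognormal(mean=mu, sigma=config.ol_length_sigma).astype(np.int64), 2_000
        )
        total = int(lengths.sum())
        if total > arm.length:
            raise ValueError(
                f"infeasible packing on arm {arm.name!r}: OL lengths sum to {total} "
                f"> arm length {arm.length}"
            )
        gaps = rng.multinomial(arm.length - total, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start, end = pos, pos + int(lengths[k])
            pos = end
            ol_id = f"OL_{arm.name}_{k}"
            n_genes = int(rng.integers(config.genes_per_ol[0], config.genes_per_ol[1] + 1))
            n_genes = max(1, min(n_genes, end - start))
            nested_flags = rng.random(n_genes) < config.nested_fraction
            nested_flags[0] = False
            n_main = int(np.count_nonzero(~nested_flags))
            width = (end - start) // n_main
            gene_ids: list[str] = []
            tile = 0
            last_main: GeneRecord | None = None
            for j in range(n_genes):
                gid = f"{ol_id}_g{j}"
                gene_ids.append(gid)
                if nested_flags[j] and last_main is not None:
                    # nested gene: an interval inside its host's span
                    span = last_main.end - last_main.start
                    gs = last_main.start + max(1, span // 4)
                    ge = min(last_main.end, gs + max(1, span // 2))
                    g = GeneRecord(gid, arm.name, gs, ge, nested_in=last_main.id)
                else:
                    gs = start + tile * width
                    ge = end if tile == n_main - 1 else gs + width
                    tile += 1
                    g = GeneRecord(gid, arm.name, gs, ge)
                    last_main = g
                genes.append(g)
            ols.append(OLRegion(ol_id, arm.name, start, end, config.definitions[0],
                                tuple(gene_ids)))
            intended_lam.append(bool(is_lam[k]))
            if is_lam[k]:
                lamin.add(gene_ids[0])

    link_nesting(genes)

    # --- tags, breakpoints, flank flags -----------------------------------
    tags = _draw_tags(rng, len(genes), config.tag_ovary, config.tag_testis)
    theta = config.testis_breakpoint_multiplier
    mu_bp = config.baseline_breakpoint_rate
    rates = np.where(tags == 2, theta * mu_bp, mu_bp)
    for d in config.definitions:
        left = rng.poisson(rates)
        right = rng.poisson(rates)
        extra_l = rng.random(len(genes)) < config.flank_change_rate
        extra_r = rng.random(len(genes)) < config.flank_change_rate
        for i, g in enumerate(genes):
            g.left_breakpoints[d] = int(left[i])
            g.right_breakpoints[d] = int(right[i])
            g.left_changed[d] = bool(left[i] > 0 or extra_l[i])
            g.right_changed[d] = bool(right[i] > 0 or extra_r[i])

    beta = config.class_tag_bias
    if beta != 1.0:
        from .synteny import classify_synteny

        d0 = config.definitions[0]
        p_o, p_t = config.tag_ovary, config.tag_testis
        p_u = 1.0 - p_o - p_t
        norm = p_o + beta * p_t + p_u
        for i, g in enumerate(genes):
            if classify_synteny(g, d0) == "bisyntenic":
                u = rng.random() * norm
                if u < p_o:
                    tags[i] = 1
                elif u < p_o + beta * p_t:
                    tags[i] = 2
                else:
                    tags[i] = 0
    for i, g in enumerate(genes):
        g.tag = _TAG_NAMES[int(tags[i])]

    probe_calls = [_probe_for(g.id, g.tag, config.probe_noise, rng) for g in genes]

    # --- CNPs --------------------------------------------------------------
    ols, _, _ = derive_lam_status(ols, lamin)
    lam_bounds: dict[str, np.ndarray] = {}
    for arm in arms:
        lam_arm = sorted(
            (o for o in ols if o.arm == arm.name and o.is_lam), key=lambda o: o.start
        )
        b = np.empty(2 * len(lam_arm), dtype=np.int64)
        for k, o in enumerate(lam_arm):
            b[2 * k] = o.start
            b[2 * k + 1] = o.end
        lam_bounds[arm.name] = b

    kinds = np.where(rng.random(config.n_cnps) < config.deletion_fraction,
                     "deletion", "duplication")
    lens = np.clip(
        rng.lognormal(config.cnp_length_mu, config.cnp_length_sigma, config.n_cnps
                      ).astype(np.int64),
        1, config.arm_length,
    )
    arm_idx = rng.integers(0, config.n_arms, size=config.n_cnps)
    lam_mult = config.lam_deletion_multiplier
    cnps: list[CNP] = []
    for i in range(config.n_cnps):
        arm = arms[int(arm_idx[i])]
        length = int(lens[i])
        weighted = kinds[i] == "deletion" and lam_mult != 1.0
        m = max(lam_mult, 1.0)
        while True:
            s = int(rng.integers(0, arm.length - length + 1))
            if not weighted:
                break
            b = lam_bounds[arm.name]
            in_lam = bool(
                (np.searchsorted(b, s, side="right") & 1)
                or (np.searchsorted(b, s + length - 1, side="right") & 1)
            )
            w = lam_mult if in_lam else 1.0
            if rng.random() < w / m:
                break
        cnps.append(CNP(f"cnp{i}", arm.name, s, s + length, str(kinds[i])))

    return Bundle(
        arms=arms, ols=ols, genes=genes, cnps=cnps,
        lamin_gene_ids=lamin, probe_calls=probe_calls, config=config,
    )


# ---------------------------------------------------------------------------
# Frozen class x tag fixture
# ---------------------------------------------------------------------------

# Published 3x2 counts (classes x (ovary-, testis-specific)) per stability
# definition; the chi-square test for trend on these reproduces 89.35 /
# 73.13 / 22.56.
TABLE1_COUNTS: dict[str, tuple[tuple[int, int], ...]] = {
    "OLC": ((32, 47), (230, 408), (295, 1336)),
    "GO": ((35, 56), (234, 449), (286, 1272)),
    "GOO": ((48, 166), (252, 488), (251, 1063)),
}

_CLASS_FLAGS = {
    "singleton": (True, True),
    "unisyntenic": (True, False),
    "bisyntenic": (False, False),
}


def make_table1_fixture(
    definition: str | None = None, tagged: bool = True
) -> list[GeneRecord]:
    """A minimal gene set whose class x tag table equals the published counts.

    With ``definition=None`` the fixture concatenates one sub-table per
    stability definition; each gene carries annotation only for its own
    definition, so per-definition analyses see exactly that column.
    ``tagged=False`` emits the same genes all untagged (zero table).
    """
    defs = DEFINITIONS if definition is None else (definition,)
    genes: list[GeneRecord] = []
    pos = 0
    for d in defs:
        for (cls, (left, right)), (n_ov, n_te) in zip(
            _CLASS_FLAGS.items(), TABLE1_COUNTS[d]
        ):
            for tag, count in (("ovary_specific", n_ov), ("testis_specific", n_te)):
                for _ in range(count):
                    bp_l, bp_r = int(left), int(right)
                    genes.append(
                        GeneRecord(
                            f"fx_{d}_{len(genes)}", "2L", pos, pos + 10,
                            left_breakpoints={d: bp_l}, right_breakpoints={d: bp_r},
                            left_changed={d: left}, right_changed={d: right},
                            tag=tag if tagged else "untagged",
                        )
                    )
                    pos += 10
    return genes
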