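"""Synthetic screen generator.

Reproduces the defining statistical structure of an in vivo pooled screen:
near-uniform library representation in the transduced cell pool, a severe
per-animal engraftment bottleneck (each dosed cell survives independently
with small probability), selective clonal outgrowth of planted hit genes to
the late timepoint, and overdispersed (Dirichlet-multinomial) sequencing.

All randomness flows from a single integer seed through spawned
``numpy.random.SeedSequence`` streams, so identical inputs give
byte-identical outputs and the bottleneck is coupled across survival
probabilities (founder sets grow monotonically with ``survival_prob``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guidescreen.counts import CountMatrix
from guidescreen.library import GuideLibrary, _random_spacers

#: Default per-cell survival probability of the lung bottleneck, calibrated so
#: the expected per-mouse representation is ~20% of the library at 50x dosing:
#: 1 - exp(-(dose/n_guides) * p) = 0.2 with dose/n_guides ~ 49.
DEFAULT_SURVIVAL_PROB = -math.log(0.8) / 49.0

CONTROL_GROUP = "cells_500x"
EARLY = "lung_4h"
LATE = "lung_19d"


class SimulationError(ValueError):
    pass


@dataclass
class ScreenDesign:
    """Experimental layout of the screen (animals, aliquots, depth)."""

    n_mice_per_group: int = 35
    timepoints: tuple[str, ...] = (EARLY, LATE)
    #: days of outgrowth per timepoint label; unlisted timepoints get 0 days
    timepoint_days: dict[str, float] = field(
        default_factory=lambda: {EARLY: 0.0, LATE: 19.0}
    )
    #: optional multi-cohort mode: ((label, n_mice), ...); each cohort gets its
    #: own control aliquots and its mice grow for ``cohort_days``
    cohorts: tuple[tuple[str, int], ...] | None = None
    cohort_days: float = 19.0
    controls_per_unit: int = 2  # aliquots per screen (or per cohort)
    control_cells: int = 5_500_000  # 500x library representation
    dose_cells: int = 550_000  # 50x per mouse
    n_transduced_cells: int = 12_000_000
    moi: float = 0.3
    read_depth: int = 1_000_000

    def __post_init__(self) -> None:
        if not self.timepoints and self.cohorts is None:
            raise SimulationError("at least one timepoint or cohort required")
        for v in (self.dose_cells, self.control_cells, self.read_depth):
            if v <= 0:
                raise SimulationError("cell and read counts must be positive")


@dataclass
class SelectionProfile:
    """Bottleneck and selection parameters of the simulation.

    ``gene_effect`` maps gene -> per-day log2 growth advantage (unlisted
    genes, including NTC, are neutral); ``guide_efficacy`` maps guide ->
    efficacy in [0, 1] (default 1).
    """

    gene_effect: dict[str, float] = field(default_factory=dict)
    guide_efficacy: dict[str, float] = field(default_factory=dict)
    survival_prob: float = DEFAULT_SURVIVAL_PROB
    dispersion: float = 0.0  # Dirichlet-multinomial overdispersion; 0 = multinomial
    sigma_clone: float = 1.0  # lognormal clone-size noise, log2 scale
    baseline_growth: float = 1.0  # doublings/day shared by all clones

    def __post_init__(self) -> None:
        if not 0.0 <= self.survival_prob <= 1.0:
            raise SimulationError("survival_prob must be in [0, 1]")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.gene_effect.get("NTC", 0.0) != 0.0:
            raise SimulationError("NTC gene effect must be 0")
        for g, x in self.guide_efficacy.items():
            if not 0.0 <= x <= 1.0:
                raise SimulationError(f"guide efficacy out of [0,1] for {g!r}")


@dataclass
class SimulatedScreen:
    counts: CountMatrix
    sample_sheet: pd.DataFrame
    truth: dict


def assign_guides_by_transduction(
    n_cells: int, moi: float, lib: GuideLibrary, seed: int
) -> pd.Series:
    """Infect ``n_cells`` at the given MOI and assign each infected cell one
    guide uniformly at random.

    Integrations per cell are Poisson(moi); cells with zero integrations are
    lost to selection. Multiply-infected cells are assigned a single guide
    (multiplets are rare at low MOI). Returns integer cell counts per guide.
    """
    if lib.n_total == 0:
        raise SimulationError("empty library")
    if n_cells <= 0:
        raise SimulationError("n_cells must be positive")
    if moi < 0:
        raise SimulationError("moi must be >= 0")
    rng = np.random.default_rng(seed)
    n_infected = int(rng.binomial(n_cells, 1.0 - math.exp(-moi)))
    probs = np.full(lib.n_total, 1.0 / lib.n_total)
    counts = rng.multinomial(n_infected, probs)
    return pd.Series(counts, index=lib.guide_ids, name="cells")


def _draw_cells(pool: np.ndarray, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n_cells without replacement from integer per-guide pool counts.

    Uses the multinomial approximation when the draw is < 1% of the pool,
    exact multivariate hypergeometric otherwise.
    """
    total = int(pool.sum())
    if n_cells > total:
        raise SimulationError(f"cannot draw {n_cells} cells from pool of {total}")
    if n_cells == 0:
        return np.zeros_like(pool)
    if n_cells == total:
        return pool.copy()
    if n_cells < 0.01 * total:
        return rng.multinomial(n_cells, pool / total)
    return rng.multivariate_hypergeometric(pool, n_cells, method="marginals")


def sample_control_aliquot(pool: pd.Series, n_cells: int, seed: int) -> pd.Series:
    """Draw an aliquot of ``n_cells`` cells from the pool."""
    rng = np.random.default_rng(seed)
    drawn = _draw_cells(pool.to_numpy(), n_cells, rng)
    return pd.Series(drawn, index=pool.index, name="cells")


def _grouped_sums(values: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Sum consecutive chunks of `values`, chunk g having length sizes[g]."""
    c = np.concatenate([[0.0], np.cumsum(values)])
    ends = np.cumsum(sizes)
    starts = ends - sizes
    return c[ends] - c[starts]


def _sequence_reads(
    mass: np.ndarray, depth: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw reads over per-guide masses: multinomial when dispersion == 0,
    Dirichlet-multinomial with concentration 1/dispersion otherwise."""
    total = mass.sum()
    if total <= 0:
        return np.zeros(len(mass), dtype=np.int64)
    props = mass / total
    if dispersion > 0:
        shape = props / dispersion  # concentration = 1/dispersion
        gam = rng.gamma(np.maximum(shape, 0.0))
        gam[shape <= 0] = 0.0
        if gam.sum() > 0:
            props = gam / gam.sum()
    return rng.multinomial(depth, props)


def simulate_mouse(
    pool: pd.Series,
    design: ScreenDesign,
    sel: SelectionProfile,
    days: float,
    seed: int,
    lib: GuideLibrary,
) -> tuple[pd.Series, set[str]]:
    """Simulate one animal: dose, bottleneck, outgrowth, sequencing.

    Returns the integer read-count column (summing to ``design.read_depth``
    when any founder exists, all zeros otherwise) and the founder guide set.
    """
    ss = np.random.SeedSequence(seed)
    rng_dose, rng_bottle, rng_growth, rng_seq = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    dosed = _draw_cells(pool.to_numpy(), design.dose_cells, rng_dose)

    # Bottleneck via shared uniforms so founder sets are coupled across p:
    # the same cell survives at p2 whenever it survived at p1 < p2.
    u = rng_bottle.random(design.dose_cells)
    survivors = _grouped_sums((u < sel.survival_prob).astype(np.float64), dosed).astype(np.int64)

    founder_ids = {g for g, s in zip(pool.index, survivors) if s > 0}
    if survivors.sum() == 0:
        return pd.Series(np.zeros(len(pool), dtype=np.int64), index=pool.index), set()

    if days > 0:
        gene_of = lib.genes  # materialize the mapping once
        genes = [gene_of[g] for g in pool.index]
        beta = np.array([sel.gene_effect.get(gn, 0.0) for gn in genes])
        x = np.array([sel.guide_efficacy.get(g, 1.0) for g in pool.index])
        log2_rate = (sel.baseline_growth + x * beta) * days
        per_founder_log2 = np.repeat(log2_rate, survivors)
        per_founder_log2 = per_founder_log2 + sel.sigma_clone * rng_growth.standard_normal(
            len(per_founder_log2)
        )
        # subtract the max for numerical stability; reads are compositional
        clone_mass = np.exp2(per_founder_log2 - per_founder_log2.max())
        mass = _grouped_sums(clone_mass, survivors)
    else:
        mass = survivors.astype(np.float64)

    reads = _sequence_reads(mass, design.read_depth, sel.dispersion, rng_seq)
    return pd.Series(reads, index=pool.index), founder_ids


def _sample_layout(design: ScreenDesign) -> list[dict]:
    """Enumerate samples: dicts with sample_id, group, days, kind, mouse_id."""
    rows: list[dict] = []
    if design.cohorts is None:
        for j in range(1, design.controls_per_unit + 1):
            rows.append(
                dict(sample_id=f"{CONTROL_GROUP}_{j}", group=CONTROL_GROUP, days=0.0,
                     kind="control", mouse_id="")
            )
        for tp in design.timepoints:
            days = design.timepoint_days.get(tp, 0.0)
            for m in range(1, design.n_mice_per_group + 1):
                rows.append(
                    dict(sample_id=f"{tp}_m{m:02d}", group=tp, days=days,
                         kind="mouse", mouse_id=f"{tp}_m{m:02d}")
                )
    else:
        for label, n_mice in design.cohorts:
            for j in range(1, design.controls_per_unit + 1):
                rows.append(
                    dict(sample_id=f"{CONTROL_GROUP}_{label}{j}", group=CONTROL_GROUP,
                         days=0.0, kind="control", mouse_id="")
                )
            for m in range(1, n_mice + 1):
                rows.append(
                    dict(sample_id=f"{label}_m{m:02d}", group=label,
                         days=design.cohort_days, kind="mouse",
                         mouse_id=f"{label}_m{m:02d}")
                )
    return rows


def simulate_screen(
    design: ScreenDesign, sel: SelectionProfile, lib: GuideLibrary, seed: int
) -> SimulatedScreen:
    """Simulate the full screen: transduced pool, control aliquots, one lung
    column per mouse per timepoint/cohort, plus sample sheet and truth record.
    """
    ss = np.random.SeedSequence(seed)
    seed_pool, seed_barcodes, seed_samples = ss.spawn(3)

    pool = assign_guides_by_transduction(
        design.n_transduced_cells, design.moi, lib, seed_pool.generate_state(1)[0]
    )
    layout = _sample_layout(design)
    n_mice = sum(1 for r in layout if r["kind"] == "mouse")
    n_controls = len(layout) - n_mice
    # expand the pool (clonal growth in culture) so aliquots + doses fit
    needed = n_controls * design.control_cells + n_mice * design.dose_cells
    total = int(pool.sum())
    if total == 0:
        raise SimulationError("transduction produced no infected cells")
    factor = max(1, math.ceil(needed / total))
    pool = pool * factor

    barcodes = _random_spacers(len(layout), 8, np.random.default_rng(seed_barcodes.generate_state(1)[0]))

    columns: dict[str, np.ndarray] = {}
    founders: dict[str, list[str]] = {}
    sheet_rows = []
    sample_seeds = seed_samples.spawn(len(layout))
    for row, bc, sseed in zip(layout, barcodes, sample_seeds):
        child = sseed.generate_state(1)[0]
        if row["kind"] == "control":
            rng = np.random.default_rng(np.random.SeedSequence(child).spawn(1)[0])
            aliquot = sample_control_aliquot(pool, design.control_cells, child)
            reads = _sequence_reads(
                aliquot.to_numpy().astype(float), design.read_depth, sel.dispersion, rng
            )
            columns[row["sample_id"]] = reads
        else:
            col, fset = simulate_mouse(pool, design, sel, row["days"], child, lib)
            columns[row["sample_id"]] = col.to_numpy()
            founders[row["sample_id"]] = sorted(fset)
        sheet_rows.append(
            dict(sample_id=row["sample_id"], barcode=bc, group=row["group"],
                 mouse_id=row["mouse_id"], run="run1")
        )

    values = pd.DataFrame(columns, index=lib.guide_ids)
    genes = pd.Series(lib.genes, name="gene").reindex(lib.guide_ids)
    groups = {r["sample_id"]: r["group"] for r in sheet_rows}
    cm = CountMatrix(values, genes, groups)
    sheet = pd.DataFrame(sheet_rows)
    truth = dict(
        planted_genes={g: b for g, b in sel.gene_effect.items() if b != 0.0},
        guide_efficacy=dict(sel.guide_efficacy),
        survival_prob=sel.survival_prob,
        founders=founders,
    )
    return SimulatedScreen(cm, sheet, truth)


def founder_representation(
    n_mice: int,
    n_guides: int = 11225,
    dose_cells: int = 550_000,
    survival_prob: float = DEFAULT_SURVIVAL_PROB,
    seed: int = 0,
) -> np.ndarray:
    """Per-mouse fraction of guides with at least one surviving founder.

    Vectorized dosing (multinomial over a uniform pool) and binomial
    bottleneck thinning; the mean fraction follows the closed form
    ``1 - exp(-(dose/n_guides) * p)``. Returns one fraction per mouse.
    """
    rng = np.random.default_rng(seed)
    probs = np.full(n_guides, 1.0 / n_guides)
    fractions = np.empty(n_mice)
    for m in range(n_mice):
        dosed = rng.multinomial(dose_cells, probs)
        survivors = rng.binomial(dosed, survival_prob)
        fractions[m] = (survivors > 0).mean()
    return fractions


# -- read generation ---------------------------------------------------------

#: constant stuffer emulating the fixed vector-homology arm between the sample
#: barcode and the protospacer in the amplicon
VECTOR_STUFFER = "TTGTGGAAAGGACGAAACACCG"


def write_screen_fastq(
    screen: SimulatedScreen,
    lib: GuideLibrary,
    path: str,
    read_length: int = 50,
    barcode_offset: int = 0,
    spacer_offset: int | None = None,
) -> dict[str, int]:
    """Write noise-free single-end reads for every sample of a simulated
    screen into one FASTQ file.

    Read layout: 8-mer sample barcode at ``barcode_offset``, constant stuffer,
    protospacer at ``spacer_offset`` (default: right after the stuffer), then
    'A' padding to ``read_length``. Returns reads written per sample.
    """
    if spacer_offset is None:
        spacer_offset = barcode_offset + 8 + len(VECTOR_STUFFER)
    if spacer_offset + lib.protospacer_length > read_length:
        raise SimulationError("spacer does not fit in the read")
    stuffer = VECTOR_STUFFER[: spacer_offset - barcode_offset - 8]
    barcode_of = dict(zip(screen.sample_sheet["sample_id"], screen.sample_sheet["barcode"]))
    spacers = {g.guide_id: g.protospacer for g in lib}
    written: dict[str, int] = {}
    qual = "I" * read_length
    with open(path, "wt", encoding="utf-8") as fh:
        for sample_id in screen.counts.sample_ids:
            bc = barcode_of[sample_id]
            col = screen.counts.values[sample_id]
            n = 0
            for guide_id, count in col.items():
                if count == 0:
                    continue
                seq = "A" * barcode_offset + bc + stuffer + spacers[guide_id]
                seq = seq + "A" * (read_length - len(seq))
                rec = f"+\n{qual}\n"
                for k in range(int(count)):
                    fh.write(f"@{sample_id}:{guide_id}:{k}\n{seq}\n{rec}")
                n += int(count)
            written[sample_id] = n
    return written
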