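"""Ground-truth colony simulator with raw qPCR output.

Generates a study-shaped data set — six colonies, three branches per colony,
ten cells per branch by default — in which each cell belongs to one of three
latent symbiont populations:

* ``homC109`` — homogeneous C109 rDNA array (C100 ratio near 0),
* ``homC100`` — near-homogeneous C100 array with trace C109 (ratio near 1),
* ``het``     — heterogeneous C100/C109 array (interior ratio), the putative
  recombinant class.

Each population has a beta-distributed intra-genomic ratio; per-cell total
rDNA copy numbers are log-uniform between roughly 500 and 30,000, with the
homogeneous-C100 class drawn from the upper half of that range.  Raw Ct
tables for the two TaqMan assays (plus optional SYBR wells with melt
temperatures) are produced from log-linear standard curves with independent
Gaussian noise on the Ct scale, so the quantification pipeline can be
exercised end to end without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .qpcr import StandardCurve, efficiency_from_slope

__all__ = [
    "SyntheticColonyConfig",
    "TrueCell",
    "DEFAULT_CURVES",
    "DEFAULT_COLONY_MIXES",
    "DEFAULT_RATIO_MODELS",
    "simulate_colonies",
    "simulate_ct_tables",
    "simulate_standard_curve_table",
    "truth_frame",
]

POPULATIONS = ("homC109", "homC100", "het")

#: latent-class ratio bounds: homC109 cells stay below, homC100 above
CLASS_T_LOW = 0.15
CLASS_T_HIGH = 0.85


def _curve(assay: str, slope: float, intercept: float) -> StandardCurve:
    return StandardCurve(assay, slope, intercept, 1.0, efficiency_from_slope(slope))


#: true calibration lines used to synthesise Ct values; efficiencies sit in
#: the 95-100% acceptance band
DEFAULT_CURVES: dict[str, StandardCurve] = {
    "C100plus": _curve("C100plus", -3.40, 40.0),
    "C100minus": _curve("C100minus", -3.38, 39.8),
    "SYBR": _curve("SYBR", -3.44, 40.5),
}

#: per-population beta models for the intra-genomic C100 ratio, taken from
#: representative fitted components: trace-C100 (C109-dominated) cells,
#: heterogeneous cells, and near-pure C100 cells
DEFAULT_RATIO_MODELS: dict[str, tuple[float, float]] = {
    "homC109": (3.48, 66.21),
    "het": (26.08, 10.89),
    "homC100": (114.8, 2.32),
}

#: study-like composition of the six default colonies
#: (homC109, homC100, het); two colonies lack the homogeneous C109 class
DEFAULT_COLONY_MIXES: tuple[tuple[float, float, float], ...] = (
    (0.050, 0.065, 0.885),
    (0.070, 0.114, 0.816),
    (0.000, 0.930, 0.070),
    (0.050, 0.280, 0.670),
    (0.050, 0.438, 0.512),
    (0.000, 0.556, 0.444),
)


@dataclass
class SyntheticColonyConfig:
    """Generative specification for a synthetic single-cell qPCR study."""

    n_colonies: int = 6
    n_branches_per_colony: int = 3
    n_cells_per_branch: int = 10
    population_mix: tuple[tuple[float, float, float], ...] = DEFAULT_COLONY_MIXES
    ratio_models: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_MODELS)
    )
    copynum_range: tuple[float, float] = (500.0, 30000.0)
    #: homogeneous-C100 cells carry more rDNA copies (upper half of the
    #: log-range); disable to probe the copy-number regression's null
    copynum_population_dependence: bool = True
    ct_noise_sd: float = 0.15
    curves: dict[str, StandardCurve] = field(default_factory=lambda: dict(DEFAULT_CURVES))
    dilution_factor: float = 1000.0
    #: ratio-preserving gain of the nested pre-amplification (24 doubling cycles)
    preamp_gain: float = 2.0**24
    include_sybr: bool = True
    tm_ref: float = 84.5
    tm_noise_sd: float = 0.2
    n_replicates: int = 2
    assay_bias: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        mixes = self.population_mix
        if len(mixes) == 1 and self.n_colonies > 1:
            mixes = tuple(mixes) * self.n_colonies
        if len(mixes) != self.n_colonies:
            raise ValueError("population_mix must give one (homC109, homC100, het) "
                             "triple per colony, or a single shared triple")
        for m in mixes:
            if len(m) != 3 or any(p < 0 for p in m) or abs(sum(m) - 1.0) > 1e-9:
                raise ValueError(f"population mix {m} must be non-negative and sum to 1")
        self.population_mix = tuple(tuple(float(p) for p in m) for m in mixes)
        lo, hi = self.copynum_range
        if not (0 < lo < hi):
            raise ValueError("copy-number range must be positive and increasing")

    def colony_ids(self) -> list[str]:
        if self.n_colonies <= 26:
            return [chr(ord("a") + i) for i in range(self.n_colonies)]
        return [f"colony{i + 1:03d}" for i in range(self.n_colonies)]


@dataclass(frozen=True)
class TrueCell:
    """Latent state of one simulated symbiont cell."""

    cell_id: str
    colony_id: str
    branch_id: str
    population: str
    true_ratio: float
    true_total_copies: float


_CLASS_BOUNDS = {
    "homC109": (0.0, CLASS_T_LOW),
    "het": (0.0, 1.0),
    "homC100": (CLASS_T_HIGH, 1.0),
}


def _draw_ratio(rng: np.random.Generator, population: str, shapes: tuple[float, float]) -> float:
    """Beta draw truncated (by resampling) to the population's ratio band."""
    lo, hi = _CLASS_BOUNDS[population]
    a, b = shapes
    for _ in range(200):
        r = float(rng.beta(a, b))
        if lo < r < hi or (population == "het" and 0 < r < 1):
            return r
    return float(np.clip(rng.beta(a, b), lo + 1e-6, hi - 1e-6))  # pragma: no cover


def simulate_colonies(
    config: SyntheticColonyConfig, rng: np.random.Generator | None = None
) -> list[TrueCell]:
    """Draw the latent cells of every configured colony.

    Populations are sampled per cell from the colony's mixture; ratios come
    from the population's beta model and total copy numbers from a
    log-uniform range (upper half for homogeneous-C100 cells when the
    copy-number dependence is enabled).  With ``rng=None`` a fresh generator
    is seeded from ``config.seed``, so repeated calls are bit-identical.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.copynum_range
    log_lo, log_hi = np.log(lo), np.log(hi)
    log_mid = 0.5 * (log_lo + log_hi)
    cells: list[TrueCell] = []
    for colony_id, mix in zip(config.colony_ids(), config.population_mix):
        for b in range(config.n_branches_per_colony):
            branch_id = f"b{b + 1}"
            for c in range(config.n_cells_per_branch):
                population = POPULATIONS[rng.choice(3, p=mix)]
                ratio = _draw_ratio(rng, population, config.ratio_models[population])
                lo_c = log_mid if (
                    population == "homC100" and config.copynum_population_dependence
                ) else log_lo
                copies = float(np.exp(rng.uniform(lo_c, log_hi)))
                cells.append(
                    TrueCell(
                        cell_id=f"cell{c + 1:02d}",
                        colony_id=colony_id,
                        branch_id=branch_id,
                        population=population,
                        true_ratio=ratio,
                        true_total_copies=copies,
                    )
                )
    return cells


def truth_frame(cells: list[TrueCell]) -> pd.DataFrame:
    """Truth table (``colony,branch,cell,population,true_ratio,true_total_copies``)."""
    return pd.DataFrame(
        {
            "colony": [c.colony_id for c in cells],
            "branch": [c.branch_id for c in cells],
            "cell": [c.cell_id for c in cells],
            "population": [c.population for c in cells],
            "true_ratio": [c.true_ratio for c in cells],
            "true_total_copies": [c.true_total_copies for c in cells],
        }
    )


def _ct_rows(rng, config, curve, copies_in_reaction, base, assay, tm):
    rows = []
    for rep in range(1, config.n_replicates + 1):
        if copies_in_reaction < 1.0:
            ct = np.nan  # below single-copy detection: non-detect well
        else:
            ct = curve.intercept + curve.slope * np.log10(copies_in_reaction)
            if config.ct_noise_sd > 0:
                ct += rng.normal(0.0, config.ct_noise_sd)
        row = dict(base, assay=assay, replicate=rep, ct=ct, tm=tm)
        rows.append(row)
    return rows


def simulate_ct_tables(
    cells: list[TrueCell],
    config: SyntheticColonyConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Raw per-well Ct table for a list of latent cells.

    Reaction template copies for each TaqMan assay are the cell's
    ratio-apportioned total, scaled by the pre-amplification gain and the
    template dilution (and any per-assay bias multiplier).  Wells receive
    independent Gaussian Ct noise; templates below one copy per reaction
    become non-detect rows (empty Ct).  SYBR rows carry a melt temperature
    near the plasmid reference; one template-free control (cell id ``NTC``)
    is emitted per colony and assay.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    scale = config.preamp_gain / config.dilution_factor
    rows: list[dict] = []
    for cell in cells:
        base = {"colony": cell.colony_id, "branch": cell.branch_id, "cell": cell.cell_id}
        targets = {
            "C100plus": cell.true_ratio * cell.true_total_copies,
            "C100minus": (1.0 - cell.true_ratio) * cell.true_total_copies,
        }
        if config.include_sybr:
            targets["SYBR"] = cell.true_total_copies
        for assay, true_copies in targets.items():
            bias = config.assay_bias.get(assay, 1.0)
            in_reaction = true_copies * scale * bias
            if assay == "SYBR":
                tm = config.tm_ref + (
                    rng.normal(0.0, config.tm_noise_sd) if config.tm_noise_sd > 0 else 0.0
                )
            else:
                tm = np.nan
            rows.extend(
                _ct_rows(rng, config, config.curves[assay], in_reaction, base, assay, tm)
            )
    for colony_id in config.colony_ids():
        base = {"colony": colony_id, "branch": "b1", "cell": "NTC"}
        assays = ["C100plus", "C100minus"] + (["SYBR"] if config.include_sybr else [])
        for assay in assays:
            for rep in range(1, config.n_replicates + 1):
                rows.append(dict(base, assay=assay, replicate=rep, ct=np.nan, tm=np.nan))
    return pd.DataFrame(
        rows, columns=["colony", "branch", "cell", "assay", "replicate", "ct", "tm"]
    )


def simulate_standard_curve_table(
    config: SyntheticColonyConfig,
    rng: np.random.Generator | None = None,
    n_levels: int = 5,
    start_copies: float = 10.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Serial-dilution calibration wells (``assay,dilution_copies,ct``).

    Five ten-fold dilutions per assay by default, measured in triplicate
    with the configured Ct noise.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rows = []
    for assay, curve in sorted(config.curves.items()):
        if assay == "SYBR" and not config.include_sybr:
            continue
        for level in range(n_levels):
            copies = start_copies * 10.0**level
            expected = curve.intercept + curve.slope * np.log10(copies)
            for _ in range(n_replicates):
                ct = expected + (
                    rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                )
                rows.append({"assay": assay, "dilution_copies": copies, "ct": ct})
    return pd.DataFrame(rows, columns=["assay", "dilution_copies", "ct"])


def with_seed(config: SyntheticColonyConfig, seed: int) -> SyntheticColonyConfig:
    """Copy of ``config`` with a different root seed."""
    return replace(config, seed=int(seed))
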