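"""Standard-curve calibration and per-cell copy-number estimation.

Two allele-specific TaqMan assays quantify a cell's ITS2 rDNA: C100+ counts
copies of ribotype C100 (``C_C100``) and C100- counts all other clade-C
copies (``C_non_C100``); their sum is the total copy number ``C_TOTAL`` and
the analysis variable is the ratio ``X = C_C100 / C_TOTAL``.  An optional
SYBR assay re-measures ``C_TOTAL`` directly, with an amplicon melt
temperature (Tm) as a specificity check.

Calibration uses log-linear standard curves (Ct regressed on log10 copies
over a serial dilution).  QC keeps a well set only if its mean Ct falls
below the curve intercept (at least one template copy), the duplicate-well
standard deviation is < 0.5 cycles and, for SYBR, the melt temperature is
within 1 degree C of the plasmid reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "WellSet",
    "CellQuant",
    "QCResult",
    "fit_standard_curve",
    "copies_from_ct",
    "ct_from_copies",
    "qc_filter",
    "quantify_cell",
    "constrained_r2",
    "mixture_test_eval",
    "read_standard_curve_table",
    "read_ct_table",
    "quantify_table",
]

#: duplicate-well Ct standard deviation threshold (cycles)
CT_SD_MAX = 0.5
#: SYBR melt-temperature tolerance around the plasmid reference (deg C)
TM_TOLERANCE = 1.0


@dataclass(frozen=True)
class StandardCurve:
    """Log-linear calibration for one assay: Ct = intercept + slope*log10(copies)."""

    assay_id: str
    slope: float
    intercept: float
    r2: float
    efficiency_pct: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")


@dataclass
class WellSet:
    """Replicate Ct readings of one assay on one cell's template solution."""

    cell_id: str
    colony_id: str
    branch_id: str
    assay_id: str
    ct_values: np.ndarray
    tm: float | None = None

    def __post_init__(self) -> None:
        self.ct_values = np.asarray(self.ct_values, dtype=float)
        self.ct_values = self.ct_values[np.isfinite(self.ct_values)]
        if np.any(self.ct_values <= 0):
            raise ValueError("Ct readings must be positive")

    @property
    def is_nondetect(self) -> bool:
        """True when no well crossed the fluorescence threshold."""
        return self.ct_values.size == 0

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_values)) if self.ct_values.size else float("nan")

    @property
    def sd_ct(self) -> float:
        if self.ct_values.size < 2:
            return 0.0
        return float(np.std(self.ct_values, ddof=1))


@dataclass
class QCResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class CellQuant:
    """Estimated per-cell copy numbers and C100 ratio."""

    cell_id: str
    colony_id: str
    branch_id: str
    c_c100: float
    c_non_c100: float
    c_total: float
    ratio: float  # NaN when the cell is excluded (both assays non-detect)
    qc_flags: list[str] = field(default_factory=list)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent, E = (10**(-1/slope) - 1) * 100."""
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(dilution_series, assay_id: str = "assay") -> StandardCurve:
    """OLS of mean Ct on log10(copies) over a serial-dilution series.

    Parameters
    ----------
    dilution_series : sequence of (copies, ct_readings)
        Known template copy number and the replicate Ct values measured at
        that level.  At least three distinct dilution levels are required.
    """
    levels = [(float(c), np.atleast_1d(np.asarray(ct, dtype=float))) for c, ct in dilution_series]
    copies = np.array([c for c, _ in levels])
    if np.unique(copies).size < 3:
        raise ValueError("standard curve needs >= 3 distinct dilution levels")
    if np.any(copies <= 0):
        raise ValueError("dilution copy numbers must be positive")
    mean_ct = np.array([ct.mean() for _, ct in levels])
    res = stats.linregress(np.log10(copies), mean_ct)
    if res.slope >= 0:
        raise ValueError("calibration failed: non-negative slope")
    return StandardCurve(
        assay_id=assay_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        efficiency_pct=float(efficiency_from_slope(res.slope)),
    )


def copies_from_ct(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: copies = 10**((ct - intercept)/slope)."""
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def ct_from_copies(copies: float, curve: StandardCurve) -> float:
    """Expected Ct for a known template copy number on ``curve``."""
    return float(curve.intercept + curve.slope * np.log10(copies))


def qc_filter(wellset: WellSet, curve: StandardCurve, tm_ref: float | None = None) -> QCResult:
    """Apply the inclusion rules to one well set.

    Pass requires mean Ct below the curve intercept (>= 1 template copy),
    duplicate SD < 0.5 cycles and, for SYBR well sets, a melt temperature
    within 1 degree C of the plasmid reference Tm.
    """
    reasons: list[str] = []
    if wellset.is_nondetect:
        return QCResult(False, ["non-detect: no well crossed threshold"])
    if not wellset.mean_ct < curve.intercept:
        reasons.append(
            f"mean Ct {wellset.mean_ct:.2f} not below curve intercept "
            f"{curve.intercept:.2f} (<1 copy)"
        )
    if not wellset.sd_ct < CT_SD_MAX:
        reasons.append(f"duplicate Ct SD {wellset.sd_ct:.3f} >= {CT_SD_MAX}")
    if wellset.assay_id == "SYBR":
        if wellset.tm is None or tm_ref is None:
            raise ValueError("SYBR well set requires tm and tm_ref")
        if not abs(wellset.tm - tm_ref) < TM_TOLERANCE:
            reasons.append(
                f"Tm {wellset.tm:.2f} outside +/-{TM_TOLERANCE} C of reference {tm_ref:.2f}"
            )
    return QCResult(passed=not reasons, reasons=reasons)


def _assay_copies(wellset: WellSet, curve: StandardCurve, scale: float) -> tuple[float, bool]:
    """Copies for one assay; non-detects and below-intercept signals count as 0."""
    if wellset.is_nondetect or wellset.mean_ct >= curve.intercept:
        return 0.0, True
    return copies_from_ct(wellset.mean_ct, curve) * scale, False


def quantify_cell(
    plus: WellSet,
    minus: WellSet,
    curves: dict[str, StandardCurve],
    dilution_factor: float = 1.0,
    preamp_gain: float = 1.0,
    assay_bias: dict[str, float] | None = None,
    qc_flags: list[str] | None = None,
) -> CellQuant:
    """Estimate one cell's copy numbers and C100 ratio from both TaqMan assays.

    Copies are computed from the mean Ct of each assay, scaled back through
    the template dilution and the (ratio-preserving) pre-amplification gain.
    A single-assay non-detect contributes 0 copies, so ratios of exactly 0
    (pure non-C100 array) and 1 are representable; when both assays are
    non-detects the ratio is undefined (NaN) and the cell is flagged
    excluded.  The ratio is invariant to ``dilution_factor`` and
    ``preamp_gain`` since both scale numerator and denominator alike.

    ``assay_bias`` optionally multiplies each assay's copies (default 1.0)
    for sensitivity analysis of pre-amplification bias.
    """
    if dilution_factor <= 0 or preamp_gain <= 0:
        raise ValueError("dilution_factor and preamp_gain must be positive")
    bias = assay_bias or {}
    scale = dilution_factor / preamp_gain
    flags = list(qc_flags or [])
    c_plus, nd_plus = _assay_copies(plus, curves[plus.assay_id], scale)
    c_minus, nd_minus = _assay_copies(minus, curves[minus.assay_id], scale)
    c_plus /= bias.get(plus.assay_id, 1.0)
    c_minus /= bias.get(minus.assay_id, 1.0)
    if nd_plus:
        flags.append(f"{plus.assay_id}: below detection (0 copies)")
    if nd_minus:
        flags.append(f"{minus.assay_id}: below detection (0 copies)")
    total = c_plus + c_minus
    if total <= 0:
        flags.append("excluded: both assays below detection")
        ratio = float("nan")
    else:
        ratio = c_plus / total
    return CellQuant(
        cell_id=plus.cell_id,
        colony_id=plus.colony_id,
        branch_id=plus.branch_id,
        c_c100=c_plus,
        c_non_c100=c_minus,
        c_total=total,
        ratio=ratio,
        qc_flags=flags,
    )


def constrained_r2(predicted, observed) -> float:
    """R-squared of observed against predicted under the fixed line y = x.

    ``R2 = 1 - SS_res / SS_tot`` with residuals taken about the identity
    line (slope 1, intercept 0).  Can be negative when the disagreement
    exceeds the total variance of the observations.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size < 3:
        raise ValueError("predicted and observed must be equal-length, n >= 3")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R2 undefined")
    return 1.0 - float(np.sum((o - p) ** 2)) / ss_tot


def mixture_test_eval(
    nominal_ratios,
    wellsets,
    curves: dict[str, StandardCurve],
) -> tuple[np.ndarray, float]:
    """Evaluate assay accuracy on constructed plasmid mixtures.

    ``wellsets`` holds one (plus, minus) well-set pair per mixture, aligned
    with ``nominal_ratios`` (the known C100 : total template proportions).
    Predicted ratios come from the same quantification logic used for cells
    (dilution 1); agreement is summarised by the slope-1/intercept-0
    constrained R2 of predicted vs nominal.
    """
    nominal = np.asarray(nominal_ratios, dtype=float)
    if len(wellsets) != nominal.size:
        raise ValueError("one (plus, minus) well-set pair required per mixture")
    predicted = []
    for plus, minus in wellsets:
        q = quantify_cell(plus, minus, curves, dilution_factor=1.0)
        if np.isnan(q.ratio):
            raise ValueError(f"mixture {plus.cell_id}: both assays below detection")
        predicted.append(q.ratio)
    predicted = np.asarray(predicted)
    return predicted, constrained_r2(nominal, predicted)


# ---------------------------------------------------------------------------
# CSV dialects

def read_standard_curve_table(path) -> dict[str, StandardCurve]:
    """Read a standard-curve CSV (``assay,dilution_copies,ct``) and fit per assay."""
    df = pd.read_csv(path)
    required = {"assay", "dilution_copies", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"standard-curve table must have columns {sorted(required)}")
    curves = {}
    for assay, grp in df.groupby("assay", sort=True):
        series = [
            (copies, sub["ct"].to_numpy())
            for copies, sub in grp.groupby("dilution_copies", sort=True)
        ]
        curves[assay] = fit_standard_curve(series, assay_id=str(assay))
    return curves


def read_ct_table(path) -> pd.DataFrame:
    """Read a per-well Ct table CSV.

    Columns: ``colony,branch,cell,assay,replicate,ct,tm``; an empty ``ct``
    marks a non-detect well, ``tm`` is empty for TaqMan rows, and
    template-free controls use cell id ``NTC``.
    """
    df = pd.read_csv(path, dtype={"colony": str, "branch": str, "cell": str, "assay": str})
    required = {"colony", "branch", "cell", "assay", "replicate", "ct", "tm"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


def _wellsets_from_group(grp: pd.DataFrame) -> dict[str, WellSet]:
    out = {}
    for assay, sub in grp.groupby("assay", sort=True):
        tm_vals = sub["tm"].dropna()
        out[str(assay)] = WellSet(
            cell_id=str(sub["cell"].iloc[0]),
            colony_id=str(sub["colony"].iloc[0]),
            branch_id=str(sub["branch"].iloc[0]),
            assay_id=str(assay),
            ct_values=sub["ct"].to_numpy(dtype=float),
            tm=float(tm_vals.mean()) if len(tm_vals) else None,
        )
    return out


def quantify_table(
    ct_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    dilution_factor: float = 1.0,
    preamp_gain: float = 1.0,
    tm_ref: float | None = None,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Quantify every cell in a Ct table; returns the CellQuant table.

    Cells failing QC in both assays, or below detection in both, are
    excluded; each exclusion appends one structured line to ``log``.  NTC
    rows are checked for contamination (any amplification logged) and
    dropped.  Output columns:
    ``colony,branch,cell,c_c100,c_non_c100,c_total,ratio,qc``.
    """
    log = log if log is not None else []
    ntc = ct_table[ct_table["cell"] == "NTC"]
    for _, row in ntc.dropna(subset=["ct"]).iterrows():
        log.append(
            f"WARN NTC amplification colony={row['colony']} assay={row['assay']} ct={row['ct']}"
        )
    cells = ct_table[ct_table["cell"] != "NTC"]
    records = []
    for (colony, branch, cell), grp in cells.groupby(["colony", "branch", "cell"], sort=True):
        ws = _wellsets_from_group(grp)
        if "C100plus" not in ws or "C100minus" not in ws:
            log.append(f"EXCLUDE cell={colony}/{branch}/{cell} rule=missing-assay")
            continue
        flags: list[str] = []
        hard_fail = False
        for assay in ("C100plus", "C100minus"):
            w = ws[assay]
            qc = qc_filter(w, curves[assay], tm_ref=tm_ref) if not w.is_nondetect else QCResult(True)
            for r in qc.reasons:
                # below-intercept means <1 copy, handled as 0 copies, not a failure
                if "not below curve intercept" in r or "non-detect" in r:
                    continue
                flags.append(f"{assay}: {r}")
                hard_fail = True
                log.append(f"EXCLUDE cell={colony}/{branch}/{cell} assay={assay} rule={r}")
        if "SYBR" in ws and tm_ref is not None and not ws["SYBR"].is_nondetect:
            qc = qc_filter(ws["SYBR"], curves["SYBR"], tm_ref=tm_ref)
            for r in qc.reasons:
                flags.append(f"SYBR: {r}")
                log.append(f"FLAG cell={colony}/{branch}/{cell} assay=SYBR rule={r}")
        if hard_fail:
            continue
        q = quantify_cell(
            ws["C100plus"], ws["C100minus"], curves,
            dilution_factor=dilution_factor, preamp_gain=preamp_gain, qc_flags=flags,
        )
        if np.isnan(q.ratio):
            log.append(f"EXCLUDE cell={colony}/{branch}/{cell} rule=both-assays-below-detection")
            continue
        records.append(
            {
                "colony": colony,
                "branch": branch,
                "cell": cell,
                "c_c100": q.c_c100,
                "c_non_c100": q.c_non_c100,
                "c_total": q.c_total,
                "ratio": q.ratio,
                "qc": ";".join(q.qc_flags) if q.qc_flags else "pass",
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["colony", "branch", "cell", "c_c100", "c_non_c100", "c_total", "ratio", "qc"],
    )
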