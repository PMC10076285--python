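"""ATR-FTIR amide-I analysis: preprocessing chain and stepwise calibration.

Preprocessing follows a fixed order on each absorbance spectrum:

1. water-vapor subtraction, scaled by least squares against a vapor
   reference over the 1956–1935 cm⁻¹ window (a quiet region of protein
   spectra where vapor lines are strong);
2. piecewise-linear baseline subtraction anchored at
   3700, 3000, 2800, 1720, 1480, 1204 and 980 cm⁻¹;
3. normalization to unit integrated area over the amide-I window
   (1720–1480 cm⁻¹).

Secondary-structure fractions (α-helix, β-sheet, turns, random coil) are
then estimated by an ascending stepwise multivariate calibration: for each
class, absorbance wavenumbers inside the amide-I window are added greedily
to a linear model as long as they reduce the residual sum of squares, up to
three wavenumbers per class.  The standard error of prediction (SEP) is the
RMS leave-one-out cross-validated prediction error, with the wavenumber
selection repeated inside every fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateReferenceError,
    GridMismatchError,
    NormalizationError,
    RankDeficiencyError,
    ValidationError,
)

logger = logging.getLogger(__name__)

AMIDE_I_WINDOW = (1480.0, 1720.0)
VAPOR_WINDOW = (1935.0, 1956.0)
BASELINE_ANCHORS = (3700.0, 3000.0, 2800.0, 1720.0, 1480.0, 1204.0, 980.0)


@dataclass
class Spectrum:
    """A single-beam absorbance spectrum on a strictly monotone grid.

    The canonical orientation is descending wavenumber (4000 → 600 cm⁻¹);
    ascending input is reversed on construction.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        self.absorbance = np.asarray(self.absorbance, float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValidationError("wavenumber and absorbance lengths differ")
        if self.wavenumbers.size < 2:
            raise ValidationError("spectrum needs at least two points")
        steps = np.diff(self.wavenumbers)
        if (steps > 0).all():
            logger.info("ascending wavenumber grid reversed to canonical order")
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.absorbance = self.absorbance[::-1].copy()
        elif not (steps < 0).all():
            raise ValidationError("wavenumber grid must be strictly monotone")

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def value_at(self, wavenumber: float) -> float:
        """Absorbance at an exact grid point (no interpolation)."""
        idx = np.flatnonzero(np.isclose(self.wavenumbers, wavenumber))
        if idx.size == 0:
            raise GridMismatchError(
                f"wavenumber {wavenumber} cm⁻¹ not on the grid"
            )
        return float(self.absorbance[idx[0]])

    def copy_with(self, absorbance: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), np.asarray(absorbance, float),
                        label=self.label)


def read_spectrum(path, label: str = "") -> Spectrum:
    """Read a two-column (wavenumber, absorbance) text spectrum.

    Both whitespace- and comma-separated layouts are accepted; lines
    starting with ``#`` are comments.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValidationError(f"malformed spectrum line: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValidationError(f"no data in spectrum file {path}")
    arr = np.asarray(rows, float)
    return Spectrum(arr[:, 0], arr[:, 1], label=label or str(path))


def write_spectrum(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("# wavenumber_cm-1 absorbance_AU\n")
        for wn, ab in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{wn:.6f} {ab:.9e}\n")


def _check_same_grid(a: Spectrum, b: Spectrum) -> None:
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.array_equal(
        a.wavenumbers, b.wavenumbers
    ):
        raise GridMismatchError(
            "spectra are on different grids; resample explicitly first"
        )


def subtract_water_vapor(
    spectrum: Spectrum,
    vapor_reference: Spectrum,
    window: tuple[float, float] = VAPOR_WINDOW,
) -> tuple[Spectrum, float]:
    """Remove the water-vapor contribution from a spectrum.

    The scaling coefficient c minimizes the residual over the reference
    window: ``c = <spectrum, reference> / <reference, reference>`` restricted
    to the window; the whole reference is then subtracted with that scale.
    Returns the corrected spectrum and c.
    """
    _check_same_grid(spectrum, vapor_reference)
    lo, hi = min(window), max(window)
    m = spectrum.window_mask(lo, hi)
    if not m.any():
        raise ValidationError("vapor scaling window outside the grid")
    ref_w = vapor_reference.absorbance[m]
    denom = float(ref_w @ ref_w)
    if denom == 0.0:
        raise DegenerateReferenceError(
            f"vapor reference carries no signal in {lo}-{hi} cm⁻¹"
        )
    c = float(spectrum.absorbance[m] @ ref_w) / denom
    out = spectrum.copy_with(spectrum.absorbance - c * vapor_reference.absorbance)
    return out, c


def baseline_correct(
    spectrum: Spectrum,
    anchors: tuple[float, ...] = BASELINE_ANCHORS,
) -> Spectrum:
    """Subtract a piecewise-linear baseline through the anchor wavenumbers.

    Straight lines are interpolated between the spectrum's values at the
    anchors and subtracted; the output is exactly zero at every anchor.
    Points outside the anchor range are left untouched (and noted in the
    log the first time).
    """
    wn = spectrum.wavenumbers
    anchor_vals = []
    for a in anchors:
        idx = np.flatnonzero(np.isclose(wn, a))
        if idx.size == 0:
            raise ValidationError(f"baseline anchor {a} cm⁻¹ not on the grid")
        anchor_vals.append(spectrum.absorbance[idx[0]])
    order = np.argsort(anchors)
    xa = np.asarray(anchors, float)[order]
    ya = np.asarray(anchor_vals, float)[order]
    inside = (wn >= xa[0]) & (wn <= xa[-1])
    if (~inside).any():
        logger.debug(
            "%d points outside the anchor range [%g, %g] left untouched",
            int((~inside).sum()), xa[0], xa[-1],
        )
    baseline = np.zeros_like(wn)
    baseline[inside] = np.interp(wn[inside], xa, ya)
    return spectrum.copy_with(spectrum.absorbance - baseline)


def amide_area(spectrum: Spectrum,
               window: tuple[float, float] = AMIDE_I_WINDOW) -> float:
    """Trapezoid integral of the spectrum over a window (AU·cm⁻¹)."""
    lo, hi = min(window), max(window)
    m = spectrum.window_mask(lo, hi)
    if m.sum() < 2:
        raise ValidationError("window covers fewer than two grid points")
    # integrate in ascending wavenumber so the area of a positive band is > 0
    x = spectrum.wavenumbers[m][::-1]
    y = spectrum.absorbance[m][::-1]
    return float(np.trapezoid(y, x))


def normalize_area(
    spectrum: Spectrum,
    window: tuple[float, float] = AMIDE_I_WINDOW,
) -> Spectrum:
    """Scale the whole spectrum so the window area equals 1 AU·cm⁻¹."""
    area = amide_area(spectrum, window)
    if area <= 0:
        raise NormalizationError(
            f"window area must be positive to normalize, got {area:.3g}"
        )
    return spectrum.copy_with(spectrum.absorbance / area)


def preprocess(
    spectrum: Spectrum,
    vapor_reference: Spectrum | None = None,
    anchors: tuple[float, ...] = BASELINE_ANCHORS,
    window: tuple[float, float] = AMIDE_I_WINDOW,
) -> Spectrum:
    """Full fixed-order chain: vapor subtraction → baseline → area normalization."""
    out = spectrum
    if vapor_reference is not None:
        out, _ = subtract_water_vapor(out, vapor_reference)
    out = baseline_correct(out, anchors)
    return normalize_area(out, window)


# --------------------------------------------------------------------------
# Stepwise calibration
# --------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """Per-class linear models on at most three selected wavenumbers."""

    classes: tuple
    wavenumbers: dict            # class -> list of selected wavenumbers (cm⁻¹)
    coefficients: dict           # class -> array [intercept, c1, c2, ...]
    sep_loocv: dict = field(default_factory=dict)  # class -> % RMS LOO error
    candidate_window: tuple = AMIDE_I_WINDOW

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "wavenumbers": {k: list(map(float, v))
                            for k, v in self.wavenumbers.items()},
            "coefficients": {k: list(map(float, v))
                             for k, v in self.coefficients.items()},
            "sep_loocv": {k: float(v) for k, v in self.sep_loocv.items()},
            "candidate_window": list(self.candidate_window),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            classes=tuple(payload["classes"]),
            wavenumbers={k: list(v) for k, v in payload["wavenumbers"].items()},
            coefficients={k: np.asarray(v, float)
                          for k, v in payload["coefficients"].items()},
            sep_loocv=payload.get("sep_loocv", {}),
            candidate_window=tuple(payload.get("candidate_window",
                                               AMIDE_I_WINDOW)),
        )


@dataclass
class SecStructEstimate:
    """Mean ± SD secondary-structure percentages over replicate spectra."""

    classes: tuple
    mean: np.ndarray
    sd: np.ndarray
    n_replicates: int
    out_of_range: np.ndarray   # bool per class: any prediction outside [0, 100]
    predictions: np.ndarray    # (n_replicates, n_classes), verbatim

    def as_dict(self) -> dict:
        return {
            cls: {"mean": float(m), "sd": float(s), "out_of_range": bool(f)}
            for cls, m, s, f in zip(self.classes, self.mean, self.sd,
                                    self.out_of_range)
        }


def _design(X: np.ndarray, cols: list[int]) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0])] + [X[:, j] for j in cols])


def _fit_rss(X: np.ndarray, y: np.ndarray, cols: list[int]):
    d = _design(X, cols)
    coef, _, _, _ = np.linalg.lstsq(d, y, rcond=None)
    resid = y - d @ coef
    return coef, float(resid @ resid)


def _stepwise_select(
    X: np.ndarray, y: np.ndarray, max_terms: int, tol: float
) -> list[int]:
    """Greedy ascending selection of design columns minimizing the RSS."""
    selected: list[int] = []
    _, rss_prev = _fit_rss(X, y, selected)
    n_cand = X.shape[1]
    while len(selected) < max_terms and rss_prev > 1e-24:
        best_j, best_rss = -1, rss_prev
        for j in range(n_cand):
            if j in selected:
                continue
            d = _design(X, selected + [j])
            if np.linalg.matrix_rank(d) < d.shape[1]:
                continue  # collinear with current selection
            _, rss = _fit_rss(X, y, selected + [j])
            if rss < best_rss:
                best_j, best_rss = j, rss
        if best_j < 0:
            if not selected:
                raise RankDeficiencyError(
                    "no candidate wavenumber adds information (collinear set)"
                )
            break
        if rss_prev > 0 and (rss_prev - best_rss) / rss_prev < tol:
            break
        selected.append(best_j)
        rss_prev = best_rss
    return selected


def stepwise_calibrate(
    library,
    max_wavenumbers: int = 3,
    candidate_window: tuple[float, float] = AMIDE_I_WINDOW,
    tol: float = 1e-4,
    loocv: bool = True,
) -> CalibrationModel:
    """Calibrate per-class fraction predictors by ascending stepwise selection.

    Parameters
    ----------
    library
        An object with ``spectra`` (list of :class:`Spectrum` on a common
        grid) and ``fractions`` ((n, n_classes) array of percentages), e.g.
        :class:`confmap.synthetic.FTIRLibrary`.
    max_wavenumbers
        Upper bound on selected wavenumbers per class (default 3).
    tol
        Relative RSS improvement below which selection stops.
    loocv
        Report the leave-one-out SEP per class, re-running the wavenumber
        selection inside each fold.
    """
    spectra = library.spectra
    fractions = np.asarray(library.fractions, float)
    classes = tuple(library.classes)
    n = len(spectra)
    if n <= max_wavenumbers + 1:
        raise ValidationError(
            f"library of {n} spectra too small for {max_wavenumbers} terms"
        )
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        _check_same_grid(spectra[0], s)
    lo, hi = min(candidate_window), max(candidate_window)
    cand_mask = (grid >= lo) & (grid <= hi)
    cand_wn = grid[cand_mask]
    X = np.vstack([s.absorbance[cand_mask] for s in spectra])

    wavenumbers, coefficients, sep = {}, {}, {}
    for ci, cls in enumerate(classes):
        y = fractions[:, ci]
        cols = _stepwise_select(X, y, max_wavenumbers, tol)
        coef, _ = _fit_rss(X, y, cols)
        wavenumbers[cls] = [float(cand_wn[j]) for j in cols]
        coefficients[cls] = coef
        if loocv:
            errs = np.empty(n)
            for i in range(n):
                keep = np.arange(n) != i
                cols_i = _stepwise_select(X[keep], y[keep], max_wavenumbers, tol)
                coef_i, _ = _fit_rss(X[keep], y[keep], cols_i)
                pred = _design(X[i:i + 1], cols_i) @ coef_i
                errs[i] = pred[0] - y[i]
            sep[cls] = float(np.sqrt(np.mean(errs**2)))
    return CalibrationModel(
        classes=classes, wavenumbers=wavenumbers, coefficients=coefficients,
        sep_loocv=sep, candidate_window=(lo, hi),
    )


def predict_fractions(
    model: CalibrationModel, replicate_spectra: list[Spectrum]
) -> SecStructEstimate:
    """Apply a calibration model to replicate spectra of one sample.

    Each replicate yields one prediction per class; the estimate is the
    mean ± SD over replicates.  Predictions outside [0, 100] % are reported
    verbatim and flagged.
    """
    if not replicate_spectra:
        raise ValidationError("no replicate spectra supplied")
    n_rep = len(replicate_spectra)
    preds = np.empty((n_rep, len(model.classes)))
    for ci, cls in enumerate(model.classes):
        wns = model.wavenumbers[cls]
        coef = np.asarray(model.coefficients[cls], float)
        for ri, spec in enumerate(replicate_spectra):
            x = np.array([spec.value_at(w) for w in wns])
            preds[ri, ci] = coef[0] + (coef[1:] @ x if len(coef) > 1 else 0.0)
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1) if n_rep > 1 else np.zeros(len(model.classes))
    oor = ((preds < 0.0) | (preds > 100.0)).any(axis=0)
    return SecStructEstimate(
        classes=model.classes, mean=mean, sd=sd, n_replicates=n_rep,
        out_of_range=oor, predictions=preds,
    )
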