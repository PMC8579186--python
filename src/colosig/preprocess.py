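"""NIR spectral pretreatments.

Scatter corrections (SNV, detrend, MSC) combined with gap-segment
derivative/smoothing codes in the WinISI ``d,g,s1,s2`` notation, where
``d`` is the derivative order, ``g`` the gap over which the difference is
taken, and ``s1``/``s2`` the running-mean smoothing segments applied
before and after differencing.  The five codes used throughout this
package's calibration grid are ``0,0,1,1`` (raw), ``1,4,4,1``,
``1,8,8,1``, ``2,5,5,1`` and ``2,10,10,1``.

All transformers follow scikit-learn conventions (``fit``/``transform``,
stateless ones fit trivially) and operate row-wise on ``(n_samples,
n_wavelengths)`` arrays of log(1/R) absorbance.  Only MSC carries state
across samples: it stores the calibration-set mean spectrum at ``fit``
time and corrects every later spectrum against that stored reference —
validation spectra are never corrected against their own mean.

Derivative edge handling shrinks the output grid: points whose smoothing
or differencing window is incomplete are dropped, and
:meth:`GapSegmentDerivative.valid_slice` reports the surviving index
range on the input grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

#: standard instrument grid: 400.0-2499.5 nm at 0.5 nm, 4200 points
WAVELENGTH_STEP_NM = 0.5
STANDARD_WAVELENGTHS = np.arange(400.0, 2500.0, WAVELENGTH_STEP_NM)

SCATTER_OPTIONS = ("none", "detrend", "snv", "snv_detrend", "msc")

#: the 5 x 5 pretreatment grid used for model development
DERIVATIVE_CODES = ((0, 0, 1, 1), (1, 4, 4, 1), (1, 8, 8, 1), (2, 5, 5, 1), (2, 10, 10, 1))


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PretreatmentSpec:
    """One cell of the pretreatment grid."""

    scatter: str = "none"
    derivative: tuple[int, int, int, int] = (0, 0, 1, 1)

    def __post_init__(self) -> None:
        if self.scatter not in SCATTER_OPTIONS:
            raise PreprocessError(f"unknown scatter correction {self.scatter!r}")
        d, g, s1, s2 = self.derivative
        if d not in (0, 1, 2):
            raise PreprocessError("derivative order must be 0, 1 or 2")
        if d > 0 and g < 1:
            raise PreprocessError("derivative gap must be >= 1 when d > 0")
        if s1 < 1 or s2 < 1:
            raise PreprocessError("smoothing segments must be >= 1")

    @property
    def label(self) -> str:
        d, g, s1, s2 = self.derivative
        return f"{self.scatter} {d},{g},{s1},{s2}"


def default_grid() -> list[PretreatmentSpec]:
    """The full 25-treatment grid (5 scatter x 5 derivative codes)."""
    return [
        PretreatmentSpec(sc, code) for sc in SCATTER_OPTIONS for code in DERIVATIVE_CODES
    ]


def _as_2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise PreprocessError("spectra must be finite")
    return X


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: per-spectrum centring and unit scaling.

    Uses the n-1 SD divisor; invariant to any affine map of a spectrum.
    """

    def fit(self, X, y=None):
        _as_2d(X)
        return self

    def transform(self, X):
        X = _as_2d(X)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd <= 0):
            raise PreprocessError("constant spectrum cannot be SNV-transformed")
        return (X - mu) / sd


class Detrend(TransformerMixin, BaseEstimator):
    """Remove a per-spectrum least-squares polynomial trend (degree 2).

    The fit is against the wavelength axis; because polynomial spaces are
    affine-invariant, an evenly spaced index grid gives the identical
    residual, so no wavelength vector is required.
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, X, y=None):
        X = _as_2d(X)
        if X.shape[1] <= self.degree:
            raise PreprocessError("spectrum shorter than detrend degree + 1")
        return self

    def transform(self, X):
        X = _as_2d(X)
        n_wl = X.shape[1]
        t = np.linspace(-1.0, 1.0, n_wl)
        basis = np.polynomial.polynomial.polyvander(t, self.degree)
        q, _ = np.linalg.qr(basis)
        return X - (X @ q) @ q.T


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a stored reference mean.

    ``fit`` stores the mean spectrum of the calibration set; ``transform``
    regresses each spectrum on that reference (``x = a + b * ref``) and
    returns ``(x - a) / b``.
    """

    def __init__(self, min_slope: float = 1e-12):
        self.min_slope = min_slope

    def fit(self, X, y=None):
        X = _as_2d(X)
        self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        X = _as_2d(X)
        ref = self.reference_
        refc = ref - ref.mean()
        denom = float(refc @ refc)
        if denom <= 0:
            raise PreprocessError("constant MSC reference")
        b = (X - X.mean(axis=1, keepdims=True)) @ refc / denom
        if np.any(np.abs(b) < self.min_slope):
            raise PreprocessError("MSC regression slope below tolerance")
        a = X.mean(axis=1) - b * ref.mean()
        return (X - a[:, None]) / b[:, None]


def _running_mean(X: np.ndarray, segment: int) -> np.ndarray:
    """Centered running mean over ``segment`` points; shrinks the row."""
    if segment == 1:
        return X
    kernel = np.ones(segment) / segment
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, X)
    return out


class GapSegmentDerivative(TransformerMixin, BaseEstimator):
    """WinISI-style gap-segment derivative ``(d, g, s1, s2)``.

    Pipeline: running-mean smoothing over ``s1`` points, gap difference,
    running-mean smoothing over ``s2`` points.  First derivative uses the
    centred difference ``a[i + ceil(g/2)] - a[i - floor(g/2)]`` (the gap
    split as evenly as possible); second derivative uses
    ``a[i+g] - 2 a[i] + a[i-g]``.  Output rows are narrower than the
    input by the combined window; :meth:`valid_slice` gives the surviving
    input-grid indices so wavelength axes can be carried along.
    """

    def __init__(self, code: tuple[int, int, int, int] = (0, 0, 1, 1)):
        self.code = code

    def _parts(self):
        d, g, s1, s2 = self.code
        PretreatmentSpec(derivative=(d, g, s1, s2))  # validation
        return d, g, s1, s2

    def valid_slice(self, n_wavelengths: int) -> slice:
        """Indices of the input grid that survive the edge shrinkage."""
        d, g, s1, s2 = self._parts()
        left = (s1 - 1) // 2 + (s2 - 1) // 2
        right = (s1 - 1) - (s1 - 1) // 2 + (s2 - 1) - (s2 - 1) // 2
        if d == 1:
            left += g // 2
            right += g - g // 2
        elif d == 2:
            left += g
            right += g
        if left + right >= n_wavelengths:
            raise PreprocessError("derivative window exceeds spectrum length")
        return slice(left, n_wavelengths - right)

    def fit(self, X, y=None):
        X = _as_2d(X)
        self.valid_slice(X.shape[1])
        return self

    def transform(self, X):
        X = _as_2d(X)
        d, g, s1, s2 = self._parts()
        self.valid_slice(X.shape[1])
        out = _running_mean(X, s1)
        if d == 1:
            lo, hi = g // 2, g - g // 2
            out = out[:, lo + hi :] - out[:, : out.shape[1] - lo - hi]
        elif d == 2:
            out = out[:, 2 * g :] - 2 * out[:, g : out.shape[1] - g] + out[:, : out.shape[1] - 2 * g]
        out = _running_mean(out, s2)
        return out


class Pretreatment(TransformerMixin, BaseEstimator):
    """Composite pretreatment: scatter correction, then derivative code.

    The scatter-before-derivative order follows the WinISI convention;
    ``snv_detrend`` applies SNV first and detrend second.  MSC state (the
    calibration mean) is fitted on the calibration set and replayed on
    any later spectra.
    """

    def __init__(self, spec: PretreatmentSpec = PretreatmentSpec()):
        self.spec = spec

    def _scatter_steps(self):
        sc = self.spec.scatter
        if sc == "none":
            return []
        if sc == "snv":
            return [SNV()]
        if sc == "detrend":
            return [Detrend()]
        if sc == "snv_detrend":
            return [SNV(), Detrend()]
        return [MSC()]

    def fit(self, X, y=None):
        X = _as_2d(X)
        self.steps_ = self._scatter_steps()
        for step in self.steps_:
            X = step.fit(X).transform(X)
        self.derivative_ = GapSegmentDerivative(self.spec.derivative).fit(X)
        self.n_wavelengths_in_ = None
        return self

    def transform(self, X):
        X = _as_2d(X)
        for step in self.steps_:
            X = step.transform(X)
        return self.derivative_.transform(X)

    def valid_slice(self, n_wavelengths: int) -> slice:
        return GapSegmentDerivative(self.spec.derivative).valid_slice(n_wavelengths)


def apply_pretreatment(X_calibration, spec: PretreatmentSpec, X_other=None):
    """Functional wrapper: fit on the calibration set, transform both.

    Returns ``(fitted Pretreatment, transformed calibration,
    transformed other-or-None)``.
    """
    pt = Pretreatment(spec).fit(X_calibration)
    Xc = pt.transform(X_calibration)
    Xo = pt.transform(X_other) if X_other is not None else None
    return pt, Xc, Xo


def snv(x):
    """Standard normal variate of one spectrum or a stack of spectra."""
    return np.squeeze(SNV().fit_transform(np.asarray(x, dtype=float)))


def detrend(x, degree: int = 2):
    return np.squeeze(Detrend(degree=degree).fit_transform(np.asarray(x, dtype=float)))


def msc(x, reference_mean):
    """MSC of ``x`` against an explicit calibration mean spectrum."""
    m = MSC()
    m.reference_ = np.asarray(reference_mean, dtype=float)
    return np.squeeze(m.transform(np.asarray(x, dtype=float)))


def gap_segment_derivative(x, code=(0, 0, 1, 1)):
    return np.squeeze(GapSegmentDerivative(code).fit_transform(np.asarray(x, dtype=float)))
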