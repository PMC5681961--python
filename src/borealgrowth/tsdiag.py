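"""Time-series model identification: ACF, CCF and the ESACF table.

The extended sample autocorrelation function (ESACF) is computed by the
iterated-autoregression recursion of Tsay & Tiao: for each AR order p the AR
coefficients are re-estimated through successive MA iterations, the series is
filtered by them, and the entry at (p, q) is the filtered series' sample
autocorrelation at lag q+1.  For an ARMA(p₀, q₀) process the table shows a
triangle of asymptotic zeros with vertex (p₀, q₀); entries are called zero
when |value| ≤ 2/√n (the standard large-sample bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf


class IdentificationError(ValueError):
    pass


@dataclass
class CorrelationFunction:
    """Sampled auto- or cross-correlations with their large-sample bound."""

    lags: np.ndarray
    values: np.ndarray
    n: int

    @property
    def bound(self) -> float:
        """Approximate 95% bound ±2/√n for a white-noise null."""
        return 2.0 / np.sqrt(self.n)

    def significant(self) -> np.ndarray:
        return np.abs(self.values) > self.bound


def acf(series, max_lag: int) -> CorrelationFunction:
    """Sample autocorrelation function (biased denominator) to ``max_lag``."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= max_lag + 2:
        raise IdentificationError(f"series length {n} too short for max_lag={max_lag}")
    if np.std(x) == 0:
        raise IdentificationError("constant series: autocorrelation undefined")
    vals = _sm_acf(x, nlags=max_lag, fft=True, adjusted=False)
    return CorrelationFunction(lags=np.arange(max_lag + 1), values=vals, n=n)


def ccf(x, y, max_lag: int, difference: bool = False) -> CorrelationFunction:
    """Cross-correlations at lags −max_lag..+max_lag.

    Sign convention: a positive lag k means x leads y, i.e. the value at +k is
    corr(x_t, y_{t+k}).  With ``difference=True`` both series are first-
    differenced before correlating (an exploratory pre-whitening option; the
    default reports the untransformed series).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise IdentificationError("ccf requires equal-length aligned series")
    if difference:
        x, y = np.diff(x), np.diff(y)
    n = len(x)
    if n <= max_lag + 2:
        raise IdentificationError(f"series length {n} too short for max_lag={max_lag}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = n * x.std() * y.std()
    if denom == 0:
        raise IdentificationError("constant series: cross-correlation undefined")
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.empty(lags.shape)
    for i, k in enumerate(lags):
        if k >= 0:
            vals[i] = np.sum(xc[: n - k] * yc[k:]) / denom
        else:
            vals[i] = np.sum(xc[-k:] * yc[: n + k]) / denom
    return CorrelationFunction(lags=lags, values=vals, n=n)


@dataclass
class EsacfTable:
    """Extended sample autocorrelations for AR orders 0..p_max, MA 0..q_max."""

    values: np.ndarray  # (p_max+1, q_max+1)
    n: int

    @property
    def p_max(self) -> int:
        return self.values.shape[0] - 1

    @property
    def q_max(self) -> int:
        return self.values.shape[1] - 1

    @property
    def bound(self) -> float:
        return 2.0 / np.sqrt(self.n)

    @property
    def simplified(self) -> np.ndarray:
        """Character grid: '0' where |value| ≤ 2/√n, else 'X'."""
        return np.where(np.abs(self.values) <= self.bound, "0", "X")

    def zero_calls(self, bartlett: bool = True) -> np.ndarray:
        """Boolean zero/non-zero calls per cell.

        With ``bartlett=True`` the threshold for cell (p, q) is the MA(q)
        large-sample band 2·√((1 + 2·Σ_{j<q} r_{p,j}²)/n) (Bartlett's formula,
        with the row's lower-lag entries standing in for the filtered series'
        autocorrelations); otherwise the flat 2/√n rule of ``simplified``.
        """
        if not bartlett:
            return np.abs(self.values) <= self.bound
        return np.abs(self.values) <= 2.0 * self._bartlett_se()

    def _bartlett_se(self) -> np.ndarray:
        cum = np.cumsum(self.values**2, axis=1)
        var = np.ones_like(self.values)
        var[:, 1:] += 2.0 * cum[:, :-1]
        return np.sqrt(var / self.n)

    def render(self) -> str:
        header = "p\\q " + " ".join(f"{q:>2d}" for q in range(self.q_max + 1))
        lines = [header]
        for p, row in enumerate(self.simplified):
            lines.append(f"{p:>3d} " + " ".join(f"{c:>2s}" for c in row))
        return "\n".join(lines)


def _ar_ols(z: np.ndarray, order: int) -> np.ndarray:
    """OLS AR(order) coefficients of a demeaned series, no intercept."""
    n = len(z)
    y = z[order:]
    X = np.column_stack([z[order - i : n - i] for i in range(1, order + 1)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < order:
        raise IdentificationError(f"singular lag regression at AR order {order}")
    return coef


def _acf_at_lag(w: np.ndarray, lag: int) -> float:
    w = w - w.mean()
    denom = np.sum(w**2)
    if denom == 0:
        raise IdentificationError("degenerate filtered series in ESACF")
    return float(np.sum(w[: len(w) - lag] * w[lag:]) / denom)


def esacf(series, p_max: int = 7, q_max: int = 8) -> EsacfTable:
    """Extended sample autocorrelation table by the iterated-AR recursion."""
    z = np.asarray(series, dtype=float)
    n = len(z)
    if n < max(50, p_max + q_max + 10):
        raise IdentificationError(
            f"series length {n} too short for ESACF with p_max={p_max}, q_max={q_max}"
        )
    z = z - z.mean()
    k_top = p_max + q_max + 1  # highest AR order consumed by the recursion

    # coef[k] at MA iteration j: iterated AR(k) estimates (1-based lag index)
    coef: dict[int, np.ndarray] = {k: _ar_ols(z, k) for k in range(1, k_top + 1)}

    table = np.empty((p_max + 1, q_max + 1))
    for q in range(q_max + 1):
        table[0, q] = _acf_at_lag(z, q + 1)

    for j in range(q_max + 1):
        if j > 0:  # one Tsay–Tiao update of every retained AR order
            new: dict[int, np.ndarray] = {}
            for k in range(1, k_top - j + 1):
                upper = coef[k + 1]
                lower = coef[k]
                if lower[k - 1] == 0:
                    raise IdentificationError("zero pivot in ESACF recursion")
                lam = upper[k] / lower[k - 1]
                shifted = np.concatenate(([-1.0], lower[: k - 1]))
                new[k] = upper[:k] - lam * shifted
            coef = new
        for p in range(1, p_max + 1):
            phi = coef[p]
            w = z[p:] - sum(phi[i] * z[p - 1 - i : n - 1 - i] for i in range(p))
            table[p, j] = _acf_at_lag(w, j + 1)
    return EsacfTable(values=table, n=n)


def suggest_arma_order(table: EsacfTable, stray_tolerance: float = 0.15,
                       bartlett: bool = True) -> tuple[int, int] | None:
    """Vertex of the zero triangle: the suggested (p, q) ARMA orders.

    For an ARMA(p, q) process the asymptotic zero region is the triangle
    {(p+i, q+i+j) : i, j ≥ 0}.  A cell qualifies as a vertex when it is itself
    zero and at most ``stray_tolerance`` of its triangle's cells are
    significant — the allowance absorbs the ~5% false-significance rate of the
    per-cell call.  Because one false call at the vertex cell invalidates the
    whole search, the vertex cell itself is tested at the 1% level (2.58 SEs);
    triangle cells keep the 95% call.  The minimal qualifying cell by
    (p+q, then p) is returned; ``None`` means no clear vertex.
    """
    zero = table.zero_calls(bartlett=bartlett)
    se = table._bartlett_se() if bartlett else np.full_like(table.values, 1.0 / np.sqrt(table.n))
    vertex_ok = np.abs(table.values) <= 2.58 * se
    candidates = []
    for p in range(table.p_max + 1):
        for q in range(table.q_max + 1):
            if not vertex_ok[p, q]:
                continue
            cells = [
                (p + i, qq)
                for i in range(table.p_max - p + 1)
                for qq in range(q + i, table.q_max + 1)
            ]
            stray = sum(1 for c in cells if not zero[c])
            if stray <= stray_tolerance * len(cells):
                candidates.append((p + q, p, q))
    if not candidates:
        return None
    _, p, q = min(candidates)
    return p, q
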