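"""Lesion information transfer: how far a mismatch perturbs mean geometry.

A mismatch ensemble is compared to a control ensemble cell by cell, where a
cell is one (relative position, helical parameter).  For each cell the
profile reports the two means, their absolute difference, SDs, standard
errors corrected for serial correlation through the integrated
autocorrelation time, an empirical two-sided tail probability of the
observed deviation under the control distribution, and a Welch mean test
with effective sample sizes.  A cell is flagged when both the tail
probability and the test p-value clear their thresholds; the transfer
range is the largest flagged |position|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TransferProfile",
    "integrated_autocorr_time",
    "effective_sample_size",
    "significance_assessment",
    "deviation_profile",
    "transfer_range",
]

TRANSLATIONAL = {"shear", "stretch", "stagger", "shift", "slide", "rise"}


def integrated_autocorr_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time tau >= 1 of a stationary series.

    tau = 1 + 2 sum_k rho_k, accumulating lags while the empirical
    autocorrelation stays above the white-noise band 2/sqrt(n); an
    uncorrelated series therefore returns ~1 and an AR(1) series with decay
    phi returns ~ (1+phi)/(1-phi).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return 1.0
    xc = x - x.mean()
    if np.all(xc == 0):
        return 1.0
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n].real
    rho = acf / acf[0]
    band = 2.0 / np.sqrt(n)
    s = 0.0
    for k in range(1, n):
        if rho[k] < band:
            break
        s += rho[k]
    return float(1.0 + 2.0 * s)


def effective_sample_size(x: np.ndarray) -> float:
    return x.size / integrated_autocorr_time(np.asarray(x, dtype=float))


def significance_assessment(mm_samples: np.ndarray,
                            control_samples: np.ndarray
                            ) -> tuple[float, float]:
    """Tail probability and Welch p-value for one cell.

    The tail probability is the empirical fraction of control snapshots
    deviating from the control mean by at least the observed |mean
    difference| (two-sided, so a zero difference gives 1).  The p-value
    tests equality of means with Welch's unequal-variance statistic using
    autocorrelation-corrected effective sample sizes.
    """
    x = np.asarray(mm_samples, dtype=float)
    y = np.asarray(control_samples, dtype=float)
    if x.size < 30 or y.size < 30:
        raise ValueError("need n >= 30 samples per ensemble")
    if np.std(y) == 0:
        raise ValueError("degenerate (constant) control sample")
    delta = abs(x.mean() - y.mean())
    tail = float(np.mean(np.abs(y - y.mean()) >= delta))
    n1 = effective_sample_size(x)
    n2 = effective_sample_size(y)
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return tail, p


@dataclass
class TransferProfile:
    """Tidy per-cell comparison of a mismatch ensemble to its control."""

    table: pd.DataFrame
    alpha: float = 0.05
    alpha_t: float = 0.01

    def cell(self, position: int, parameter: str) -> pd.Series:
        t = self.table
        m = (t["position"] == position) & (t["parameter"] == parameter)
        if not m.any():
            raise KeyError(f"no cell ({position}, {parameter})")
        return t[m].iloc[0]

    def flagged_cells(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]

    def split_by_kind(self) -> dict[str, pd.DataFrame]:
        """Translational (A) and rotational (deg) parameters separately."""
        return {k: v for k, v in self.table.groupby("kind")}


def deviation_profile(mm_series: dict[str, np.ndarray],
                      control_series: dict[str, np.ndarray],
                      positions: np.ndarray,
                      alpha: float = 0.05, alpha_t: float = 0.01,
                      fdr: bool = False) -> TransferProfile:
    """Per-cell deviation profile of a mismatch ensemble vs its control.

    ``mm_series``/``control_series`` map parameter names to (frames x
    positions) arrays on a shared ``positions`` grid of relative
    coordinates (lesion pair = 0).  Optional Benjamini-Hochberg correction
    of the Welch p-values is applied across cells when ``fdr`` is set.
    """
    positions = np.asarray(positions, dtype=int)
    if set(mm_series) != set(control_series):
        raise ValueError("mismatch and control parameter sets differ")
    rows = []
    for param in mm_series:
        X = np.asarray(mm_series[param], dtype=float)
        Y = np.asarray(control_series[param], dtype=float)
        if X.shape[1] != positions.size or Y.shape[1] != positions.size:
            raise ValueError(f"{param}: series do not match the position grid")
        for j, pos in enumerate(positions):
            x = X[:, j]
            y = Y[:, j]
            tail, p = significance_assessment(x, y)
            n1 = effective_sample_size(x)
            n2 = effective_sample_size(y)
            rows.append({
                "position": int(pos),
                "parameter": param,
                "kind": ("translational" if param in TRANSLATIONAL
                         else "rotational"),
                "mean_mm": x.mean(),
                "mean_control": y.mean(),
                "abs_deviation": abs(x.mean() - y.mean()),
                "sd_mm": x.std(ddof=1),
                "sd_control": y.std(ddof=1),
                "se_mm": x.std(ddof=1) / np.sqrt(n1),
                "se_control": y.std(ddof=1) / np.sqrt(n2),
                "se_mm_naive": x.std(ddof=1) / np.sqrt(x.size),
                "n_eff_mm": n1,
                "n_eff_control": n2,
                "tail_probability": tail,
                "p_value": p,
            })
    table = pd.DataFrame(rows)
    if fdr:
        table["p_value_adj"] = _benjamini_hochberg(table["p_value"].to_numpy())
        p_for_flag = table["p_value_adj"]
    else:
        p_for_flag = table["p_value"]
    table["flagged"] = (table["tail_probability"] <= alpha) & \
                       (p_for_flag <= alpha_t)
    return TransferProfile(table=table, alpha=alpha, alpha_t=alpha_t)


def series_from_analysis(analysis, mm_position: int, kind: str = "inter"
                         ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Extract (frames x positions) series grids from a trajectory analysis.

    Positions are relative coordinates with the lesion pair at 0; for step
    parameters a step is labelled by its 5' pair, so the step at relative
    position +4 joins pairs +4 and +5.
    """
    from .params import INTER_NAMES, INTRA_NAMES  # local to avoid cycle

    if kind == "inter":
        names, data = INTER_NAMES, analysis.inter
    elif kind == "intra":
        names, data = INTRA_NAMES, analysis.intra
    else:
        raise ValueError("kind must be 'intra' or 'inter'")
    n_pos = data.shape[1]
    positions = np.arange(n_pos) - mm_position
    series = {name: data[:, :, j] for j, name in enumerate(names)}
    return series, positions


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def transfer_range(profile: TransferProfile) -> dict:
    """Flagged cells and how far the perturbation reaches.

    Returns the flagged (position, parameter) cells and the maximum |relative
    position| among them (0 when nothing is flagged).
    """
    if profile.table.empty:
        raise ValueError("empty profile")
    flagged = profile.flagged_cells()
    cells = [(int(r["position"]), r["parameter"])
             for _, r in flagged.iterrows()]
    rng = int(max((abs(c[0]) for c in cells), default=0))
    return {"flagged": cells, "range": rng,
            "n_flagged": len(cells),
            "alpha": profile.alpha, "alpha_t": profile.alpha_t}
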