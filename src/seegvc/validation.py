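"""Model-validation statistics: scaling-factor fit, error tables, cumulative
distributions, and distance-binned summaries.

The simulated potentials carry an arbitrary overall amplitude (unknown
stimulation strength plus sampling-related peak attenuation), so a single
multiplicative scaling factor is fitted by minimizing the summed absolute
error between measured and scaled simulated potentials; the exact minimizer
of  sum_i |m_i - s*x_i|  is the |x|-weighted median of the ratios m_i/x_i.
Absolute errors are normalized by the RMS over time and channels of the
preprocessed recording to yield relative (percent) errors, summarized as
empirical CDFs/percentiles and as quartile statistics over 5 mm bins of the
stimulation-to-recording distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from seegvc.phantom import ElectrodeSet, StimulationPlan


def _paired_entries(measured: pd.DataFrame, simulated: pd.DataFrame):
    """Aligned finite (measured, simulated) value pairs."""
    if not measured.index.equals(simulated.index) or not measured.columns.equals(
        simulated.columns
    ):
        sim = simulated.reindex(index=measured.index, columns=measured.columns)
        if sim.isna().to_numpy().all():
            raise ValueError("measured and simulated tables share no (pair, channel) index")
        simulated = sim
    m = measured.to_numpy(float).ravel()
    x = simulated.to_numpy(float).ravel()
    ok = np.isfinite(m) & np.isfinite(x)
    return m[ok], x[ok]


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value v with cumulative weight(values <= v) >= half the total.

    This is the exact minimizer of sum_i w_i |v_i - s| attained at a data
    point (lower weighted median).
    """
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def fit_scale(
    measured: pd.DataFrame | list[pd.DataFrame],
    simulated: pd.DataFrame | list[pd.DataFrame],
    pool: bool = True,
) -> float:
    """Scaling factor minimizing sum |measured - s * simulated| over all
    aligned entries, computed exactly as the |x|-weighted median of the
    ratios m/x (entries with x = 0 are excluded from the fit).

    Lists of tables are pooled into one fit (``pool=True``, the default,
    mirrors sharing one factor across datasets and model levels); with
    ``pool=False`` a list returns one factor per table pair.
    """
    if isinstance(measured, pd.DataFrame):
        measured, simulated = [measured], [simulated]
    if not pool:
        return [fit_scale(m, x, pool=True) for m, x in zip(measured, simulated)]
    ms, xs = [], []
    for mt, xt in zip(measured, simulated):
        m, x = _paired_entries(mt, xt)
        ms.append(m)
        xs.append(x)
    m = np.concatenate(ms)
    x = np.concatenate(xs)
    nz = x != 0
    if not nz.any():
        raise ValueError("all simulated values are zero; scale is unidentifiable")
    return weighted_median(m[nz] / x[nz], np.abs(x[nz]))


def l1_objective(measured, simulated, s: float) -> float:
    m, x = _paired_entries(measured, simulated)
    return float(np.abs(m - s * x).sum())


def fit_scale_l2(measured, simulated) -> float:
    """Least-squares variant of the scale fit (sensitivity checks only)."""
    m, x = _paired_entries(measured, simulated)
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("all simulated values are zero; scale is unidentifiable")
    return float(m @ x) / denom


def error_tables(
    measured: pd.DataFrame,
    simulated: pd.DataFrame,
    scale: float,
    rms_uV: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Absolute error |m - s*x| in uV and relative error 100*abs/rms in %.

    Inputs are in volts; ``rms_uV`` is the RMS normalizer in microvolts.
    """
    if rms_uV <= 0:
        raise ValueError("rms_uV must be positive")
    if not measured.index.equals(simulated.index) or not measured.columns.equals(
        simulated.columns
    ):
        raise ValueError("measured and simulated tables must share their index")
    abs_uV = (measured - scale * simulated).abs() * 1e6
    rel_pct = 100.0 * abs_uV / rms_uV
    return abs_uV, rel_pct


def cdf_and_percentile(abs_error: pd.DataFrame, q: float = 0.8):
    """Empirical CDF over all finite entries pooled across pairs and
    channels, and the smallest value whose cumulative fraction reaches q."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    vals = abs_error.to_numpy(float).ravel()
    vals = np.sort(vals[np.isfinite(vals)])
    if len(vals) == 0:
        raise ValueError("no finite entries in the error table")
    frac = np.arange(1, len(vals) + 1) / len(vals)
    k = int(np.ceil(q * len(vals))) - 1
    return (vals, frac), float(vals[k])


def stimulation_recording_distances(
    table: pd.DataFrame, electrodes: ElectrodeSet, plan: StimulationPlan
) -> pd.DataFrame:
    """Euclidean distance (mm) between the stimulation-pair midpoint and the
    bipolar-channel midpoint for every table entry."""
    mids = plan.pair_midpoints(electrodes)
    chan_mid = {}
    for cid in table.columns:
        a, b = cid.split("|")
        chan_mid[cid] = 0.5 * (electrodes.position(a) + electrodes.position(b))
    out = pd.DataFrame(index=table.index, columns=table.columns, dtype=float)
    for pid in table.index:
        pm = mids[pid]
        for cid in table.columns:
            out.loc[pid, cid] = float(np.linalg.norm(chan_mid[cid] - pm))
    return out


def distance_bin_stats(
    rel_error: pd.DataFrame,
    electrodes: ElectrodeSet,
    plan: StimulationPlan,
    bin_mm: float = 5.0,
) -> pd.DataFrame:
    """Quartile summaries of the relative error in ``bin_mm`` distance bins.

    Bins partition [0, max distance) as [k*bin, (k+1)*bin); per bin the
    count, median and linear-interpolation quartiles are reported; empty
    trailing bins are dropped.
    """
    dist = stimulation_recording_distances(rel_error, electrodes, plan)
    d = dist.to_numpy(float).ravel()
    e = rel_error.to_numpy(float).ravel()
    ok = np.isfinite(d) & np.isfinite(e)
    d, e = d[ok], e[ok]
    rows = []
    if len(d):
        n_bins = int(np.floor(d.max() / bin_mm)) + 1
        idx = np.floor(d / bin_mm).astype(int)
        for k in range(n_bins):
            vals = e[idx == k]
            rows.append(
                {
                    "bin_lo_mm": k * bin_mm,
                    "bin_hi_mm": (k + 1) * bin_mm,
                    "n": int(len(vals)),
                    "median": float(np.median(vals)) if len(vals) else np.nan,
                    "q1": float(np.percentile(vals, 25)) if len(vals) else np.nan,
                    "q3": float(np.percentile(vals, 75)) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["bin_lo_mm", "bin_hi_mm", "n", "median", "q1", "q3"])


@dataclass
class ValidationReport:
    """Model--measurement mismatch summary for one model level."""

    model_level: str
    scale_factor: float
    rms_uV: float
    abs_error_uV: pd.DataFrame
    rel_error_pct: pd.DataFrame
    cdf_values_uV: np.ndarray
    cdf_fractions: np.ndarray
    percentile80_uV: float
    distance_bins: pd.DataFrame

    def median_rel_error_pct(self) -> float:
        vals = self.rel_error_pct.to_numpy(float).ravel()
        return float(np.median(vals[np.isfinite(vals)]))

    def to_dict(self) -> dict:
        def df_records(df):
            out = df.where(pd.notna(df), None)
            return {
                "index": [str(i) for i in df.index],
                "columns": [str(c) for c in df.columns],
                "values": [[None if v is None else float(v) for v in row]
                           for row in out.to_numpy().tolist()],
            }

        return {
            "model_level": self.model_level,
            "scale_factor": float(self.scale_factor),
            "rms_uV": float(self.rms_uV),
            "abs_error_uV": df_records(self.abs_error_uV),
            "rel_error_pct": df_records(self.rel_error_pct),
            "cdf_values_uV": [float(v) for v in self.cdf_values_uV],
            "cdf_fractions": [float(v) for v in self.cdf_fractions],
            "percentile80_uV": float(self.percentile80_uV),
            "distance_bins": {
                "columns": list(self.distance_bins.columns),
                "values": [
                    [None if (isinstance(v, float) and np.isnan(v)) else v for v in row]
                    for row in self.distance_bins.to_numpy().tolist()
                ],
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationReport":
        def df(rec):
            return pd.DataFrame(
                np.array(
                    [[np.nan if v is None else v for v in row] for row in rec["values"]],
                    dtype=float,
                ),
                index=rec["index"],
                columns=rec["columns"],
            )

        bins = pd.DataFrame(
            [[np.nan if v is None else v for v in row] for row in d["distance_bins"]["values"]],
            columns=d["distance_bins"]["columns"],
        )
        if len(bins):
            bins["n"] = bins["n"].astype(int)
        return cls(
            model_level=d["model_level"],
            scale_factor=d["scale_factor"],
            rms_uV=d["rms_uV"],
            abs_error_uV=df(d["abs_error_uV"]),
            rel_error_pct=df(d["rel_error_pct"]),
            cdf_values_uV=np.array(d["cdf_values_uV"], dtype=float),
            cdf_fractions=np.array(d["cdf_fractions"], dtype=float),
            percentile80_uV=d["percentile80_uV"],
            distance_bins=bins,
        )

    @classmethod
    def from_json(cls, s: str) -> "ValidationReport":
        return cls.from_dict(json.loads(s))


def build_report(
    measured: pd.DataFrame,
    simulated_by_level: dict[str, pd.DataFrame],
    rms_v: float,
    electrodes: ElectrodeSet,
    plan: StimulationPlan,
    pool: bool = True,
    scale: float | None = None,
    q: float = 0.8,
    bin_mm: float = 5.0,
) -> dict[str, ValidationReport]:
    """One validation report per model level against a shared measured table.

    With ``pool=True`` (default) a single scaling factor is shared by all
    model levels, so the level comparison differs only through the simulated
    potentials; the shared factor is fitted on the most detailed level
    present (5C > 4C > 3C).  ``pool=False`` fits per level; ``scale``
    overrides the fit entirely.
    """
    levels = list(simulated_by_level)
    if scale is None and pool:
        ranking = {"5C": 0, "4C": 1, "3C": 2}
        ref = min(levels, key=lambda h: ranking.get(h, 99))
        scale_shared = fit_scale(measured, simulated_by_level[ref])
    reports = {}
    rms_uV = rms_v * 1e6
    for level in levels:
        sim = simulated_by_level[level]
        if scale is not None:
            s = scale
        elif pool:
            s = scale_shared
        else:
            s = fit_scale(measured, sim)
        abs_uV, rel_pct = error_tables(measured, sim, s, rms_uV)
        (cdf_v, cdf_f), p80 = cdf_and_percentile(abs_uV, q=q)
        bins = distance_bin_stats(rel_pct, electrodes, plan, bin_mm=bin_mm)
        reports[level] = ValidationReport(
            model_level=level,
            scale_factor=s,
            rms_uV=rms_uV,
            abs_error_uV=abs_uV,
            rel_error_pct=rel_pct,
            cdf_values_uV=cdf_v,
            cdf_fractions=cdf_f,
            percentile80_uV=p80,
            distance_bins=bins,
        )
    return reports
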