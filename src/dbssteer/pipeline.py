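"""Experiment orchestration, summary statistics and report tables.

Runs the full steering-comparison grid - nine target radii (2.00-4.00 mm in
0.25 mm steps) x the standard pulse-amplitude distributions (ring mode, five
two-electrode fractionalizations, single electrode) x the MICC and
Interleaving/MSS paradigms - and emits per-cell metrics, battery currents,
summary tables and hypothesis tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .energy import (EnergyParams, current_draw_micc, current_draw_interleaving,
                     current_draw_coactivation, round_report)
from .metrics import (cross_section, equal_area_bisector, vta_radius,
                      expected_rotation_angle, rotation_deviation, vta_volume,
                      overlap_percent)
from .vta import SteeringModel, vta_union, vta_intersection

__all__ = [
    "RING_DISTRIBUTION", "SINGLE_DISTRIBUTION", "FRACTIONALIZATIONS",
    "ExperimentGrid", "run_grid", "summarize_median_iqr",
    "wilcoxon_signed_rank", "paired_t_test", "ks_normality",
    "report_tables", "paradigm_comparisons", "headline_summaries",
]

# standard pulse-amplitude distributions (signed percentages per electrode)
RING_DISTRIBUTION: dict[int, float] = {2: -34.0, 3: -33.0, 4: -33.0}
SINGLE_DISTRIBUTION: dict[int, float] = {2: -100.0}
FRACTIONALIZATIONS: dict[str, dict[int, float]] = {
    "-50/-50": {2: -50.0, 3: -50.0},
    "-60/-40": {2: -60.0, 3: -40.0},
    "-70/-30": {2: -70.0, 3: -30.0},
    "-80/-20": {2: -80.0, 3: -20.0},
    "-90/-10": {2: -90.0, 3: -10.0},
}

SENTINEL = "---"


@dataclass
class ExperimentGrid:
    """The radius x distribution x paradigm grid to simulate."""

    target_radii: tuple[float, ...] = tuple(np.round(np.arange(2.0, 4.01, 0.25), 2))
    fractionalizations: dict[str, dict[int, float]] = field(
        default_factory=lambda: dict(FRACTIONALIZATIONS))
    include_ring: bool = True
    include_single: bool = True
    impedance_kohm: float = 3.0

    def __post_init__(self) -> None:
        for label, d in self.fractionalizations.items():
            if abs(sum(abs(v) for v in d.values()) - 100.0) > 1e-9:
                raise ValueError(f"distribution {label} does not sum to 100%")


def _metrics_for(vta, model: SteeringModel, expected_deg: float | None):
    cs = cross_section(vta, z_plane=model.z_center)
    if cs.is_empty:
        return dict(rotation_deg=np.nan, deviation_deg=np.nan, radius_mm=0.0,
                    empty=True)
    ang = equal_area_bisector(cs)
    out = dict(rotation_deg=ang, radius_mm=vta_radius(cs, ang), empty=False)
    out["deviation_deg"] = (rotation_deviation(ang, expected_deg)
                            if expected_deg is not None else np.nan)
    return out


def run_grid(model: SteeringModel | None = None,
             grid: ExperimentGrid | None = None,
             params: EnergyParams | None = None,
             progress: bool = False) -> pd.DataFrame:
    """Titrate, build and characterize every grid cell; deterministic.

    Returns one row per (paradigm, distribution, target radius) with the
    titrated amplitude, rotation/deviation/radius metrics, volumes,
    ring-overlap and intersection percentages, and equal-impedance battery
    currents.  Titration failures are recorded per cell and the run continues.
    """
    import sys

    grid = grid or ExperimentGrid()
    params = params or EnergyParams()
    model = model or SteeringModel()
    if model.activation is None:
        model.calibrate()
    z = grid.impedance_kohm
    rows: list[dict] = []

    def log(msg):
        if progress:
            print(msg, file=sys.stderr)

    for radius in grid.target_radii:
        ring_vta = None
        if grid.include_ring:
            log(f"[grid] ring mode, r={radius:.2f} mm")
            try:
                a = model.titrate(RING_DISTRIBUTION, radius, "micc")
                ring_vta = model.build_micc_vta(RING_DISTRIBUTION, a, radius)
                amps = [abs(p) / 100.0 * a for p in RING_DISTRIBUTION.values()]
                rows.append(dict(
                    paradigm="ring_mode", distribution="ring",
                    target_radius_mm=radius, amplitude_mA=a,
                    volume_mm3=vta_volume(ring_vta),
                    current_uA=current_draw_micc(amps, [z] * 3, params),
                    coactivation_uA=current_draw_coactivation(a, [z] * 3, params),
                    **_metrics_for(ring_vta, model, None)))
            except ValueError as err:
                rows.append(dict(paradigm="ring_mode", distribution="ring",
                                 target_radius_mm=radius, error=str(err)))

        if grid.include_single:
            log(f"[grid] single electrode, r={radius:.2f} mm")
            try:
                a = model.titrate(SINGLE_DISTRIBUTION, radius, "micc")
                v = model.build_micc_vta(SINGLE_DISTRIBUTION, a, radius)
                rows.append(dict(
                    paradigm="single_electrode", distribution="single",
                    target_radius_mm=radius, amplitude_mA=a,
                    volume_mm3=vta_volume(v),
                    current_uA=current_draw_micc([a], [z], params),
                    **_metrics_for(v, model, 0.0)))
            except ValueError as err:
                rows.append(dict(paradigm="single_electrode", distribution="single",
                                 target_radius_mm=radius, error=str(err)))

        for label, dist in grid.fractionalizations.items():
            expected = expected_rotation_angle(dist)
            fr = sorted((abs(p) / 100.0 for p in dist.values()), reverse=True)
            uniform = abs(fr[0] - fr[1]) < 1e-12

            log(f"[grid] micc {label}, r={radius:.2f} mm")
            try:
                a = model.titrate(dist, radius, "micc")
                v = model.build_micc_vta(dist, a, radius)
                row = dict(paradigm="micc", distribution=label,
                           target_radius_mm=radius, amplitude_mA=a,
                           expected_deg=expected, volume_mm3=vta_volume(v),
                           current_uA=current_draw_micc(
                               [a * fr[0], a * fr[1]], [z, z], params),
                           **_metrics_for(v, model, expected))
                if ring_vta is not None and not v.is_empty:
                    row["overlap_ring_pct"] = overlap_percent(v, ring_vta)
                if uniform:
                    row["coactivation_uA"] = current_draw_coactivation(
                        a, [z, z], params)
                rows.append(row)
            except ValueError as err:
                rows.append(dict(paradigm="micc", distribution=label,
                                 target_radius_mm=radius, error=str(err)))
                v = None

            log(f"[grid] interleaving {label}, r={radius:.2f} mm")
            try:
                a = model.titrate(dist, radius, "interleaving")
                vtas = model.build_interleaving_vtas(dist, a, radius)
                v1, v2 = vtas["vta1"], vtas["vta2"]
                if v1 is None:
                    raise ValueError("interleaving produced no VTA at all")
                union = vta_union(v1, v2) if v2 is not None else v1
                row = dict(paradigm="interleaving", distribution=label,
                           target_radius_mm=radius, amplitude_mA=a,
                           expected_deg=expected, volume_mm3=vta_volume(union),
                           vta2_absent=v2 is None,
                           current_uA=current_draw_interleaving(
                               [a * fr[0], a * fr[1]], [z, z], params),
                           **_metrics_for(union, model, expected))
                if v2 is not None:
                    inter = vta_intersection(v1, v2)
                    row["intersection_volume_mm3"] = vta_volume(inter)
                    row["intersection_pct"] = (100.0 * vta_volume(inter)
                                               / vta_volume(union))
                if ring_vta is not None and not union.is_empty:
                    row["overlap_ring_pct"] = overlap_percent(union, ring_vta)
                if v is not None and not v.is_empty and not union.is_empty:
                    row["overlap_micc_pct"] = overlap_percent(union, v)
                rows.append(row)
            except ValueError as err:
                rows.append(dict(paradigm="interleaving", distribution=label,
                                 target_radius_mm=radius, error=str(err)))

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summary statistics and hypothesis tests

def summarize_median_iqr(values) -> dict:
    """Median and (25-75%) quartiles by linear interpolation."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, med, q75 = np.percentile(v, [25, 50, 75], method="linear")
    return {"median": float(med), "q25": float(q25), "q75": float(q75)}


_ALT = {"two_sided": "two-sided", "two-sided": "two-sided",
        "less": "less", "greater": "greater"}


def wilcoxon_signed_rank(x, y=None, alternative: str = "two_sided") -> dict:
    """Wilcoxon signed-rank test on paired samples (or on x as differences).

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 (falling back to the normal approximation when ties make the
    exact distribution unavailable).  If every difference is zero the test is
    degenerate and p = 1 is returned with a warning.
    """
    alt = _ALT[alternative]
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; returning p = 1",
                      stacklevel=2)
        return {"statistic": 0.0, "p": 1.0, "n": 0}
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = sps.wilcoxon(d, alternative=alt, method=method)
    except (ValueError, TypeError):
        res = sps.wilcoxon(d, alternative=alt, method="approx")
    return {"statistic": float(res.statistic), "p": float(res.pvalue),
            "n": int(d.size)}


def paired_t_test(x, y, alternative: str = "two_sided") -> dict:
    """Paired-sample t test; errors on fewer than 2 pairs or zero-variance
    differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    if np.allclose(d, d[0]) and np.isclose(np.var(d), 0.0):
        if np.isclose(d[0], 0.0):
            return {"t": 0.0, "p": 1.0, "n": int(x.size)}
        raise ValueError("zero-variance non-zero differences: t undefined")
    res = sps.ttest_rel(x, y, alternative=_ALT[alternative])
    return {"t": float(res.statistic), "p": float(res.pvalue), "n": int(x.size)}


def ks_normality(values) -> dict:
    """Kolmogorov-Smirnov normality test with estimated mean/sd
    (Lilliefors-corrected critical values)."""
    v = np.asarray(values, float)
    if v.size < 5:
        raise ValueError("normality test needs at least 5 values")
    if np.isclose(np.std(v), 0.0):
        raise ValueError("degenerate (constant) sample")
    d, p = lilliefors(v, dist="norm", pvalmethod="table")
    return {"D": float(d), "p": float(p), "n": int(v.size)}


# ---------------------------------------------------------------------------
# report tables

def _fmt_cell(values, decimals=1) -> str:
    vals = [v for v in np.atleast_1d(np.asarray(values, float)) if np.isfinite(v)]
    if not vals:
        return SENTINEL
    s = summarize_median_iqr(vals)
    f = f"%.{decimals}f"
    return f"{f % s['median']} ({f % s['q25']}-{f % s['q75']})"


def report_tables(results: pd.DataFrame, outdir) -> dict[str, Path]:
    """Emit CSV analogues of the five summary tables plus the raw per-cell file.

    Cells with no value (e.g. an absent intersection VTA) are rendered with
    the ``---`` sentinel rather than dropped.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fracs = [l for l in FRACTIONALIZATIONS if l in set(results["distribution"])]
    radii = sorted(results["target_radius_mm"].dropna().unique())

    def cells_by_frac(paradigm, column, decimals=1):
        out = {}
        for l in fracs:
            sub = results[(results["paradigm"] == paradigm)
                          & (results["distribution"] == l)]
            out[l] = _fmt_cell(sub[column]) if column in sub else SENTINEL
        return out

    # deviations from the expected rotation angle
    t2 = pd.DataFrame([cells_by_frac("micc", "deviation_deg"),
                       cells_by_frac("interleaving", "deviation_deg")],
                      index=["MICC", "Interleaving/MSS"])
    # overlap with ring mode, and intersection share of the union VTA
    t3 = pd.DataFrame([cells_by_frac("micc", "overlap_ring_pct"),
                       cells_by_frac("interleaving", "overlap_ring_pct"),
                       cells_by_frac("interleaving", "intersection_pct")],
                      index=["MICC", "Interleaving/MSS", "Intersection VTA"])

    def cells_by_radius(df, paradigm, column, decimals=1):
        out = {}
        for r in radii:
            sub = df[(df["paradigm"] == paradigm)
                     & (df["target_radius_mm"] == r)]
            out[f"{r:.2f}"] = _fmt_cell(sub[column], decimals) \
                if column in sub else SENTINEL
        return out

    def tbl_by_radius(df, column, decimals=1):
        return pd.DataFrame(
            [cells_by_radius(df, "ring_mode", column, decimals),
             cells_by_radius(df, "single_electrode", column, decimals),
             cells_by_radius(df, "micc", column, decimals),
             cells_by_radius(df, "interleaving", column, decimals)],
            index=["Ring mode", "Single electrode", "MICC", "Interleaving/MSS"])

    t4 = tbl_by_radius(results, "volume_mm3")
    t4.loc["Intersection VTA"] = pd.Series(
        cells_by_radius(results, "interleaving", "intersection_volume_mm3"))
    t5 = tbl_by_radius(results, "amplitude_mA", decimals=2)
    res_rounded = results.copy()
    if "current_uA" in res_rounded:
        res_rounded["current_uA"] = res_rounded["current_uA"].map(
            lambda v: round_report(v) if np.isfinite(v) else v)
    t6 = tbl_by_radius(res_rounded, "current_uA")

    for name, tbl in [("table2_deviation_deg", t2), ("table3_overlap_pct", t3),
                      ("table4_volumes_mm3", t4), ("table5_amplitudes_mA", t5),
                      ("table6_currents_uA", t6)]:
        p = outdir / f"{name}.csv"
        tbl.to_csv(p)
        paths[name] = p
    p = outdir / "results_raw.csv"
    results.to_csv(p, index=False)
    paths["raw"] = p
    return paths


# ---------------------------------------------------------------------------
# paradigm comparisons and headline summaries

def paradigm_comparisons(results: pd.DataFrame) -> pd.DataFrame:
    """Per-fractionalization one-sided tests mirroring the study design:
    MICC lower deviation, MICC larger volume (across radii); per-radius MICC
    lower amplitude and current (across fractionalizations)."""
    rows = []
    for label in FRACTIONALIZATIONS:
        m = results[(results["paradigm"] == "micc")
                    & (results["distribution"] == label)].sort_values(
                        "target_radius_mm")
        i = results[(results["paradigm"] == "interleaving")
                    & (results["distribution"] == label)].sort_values(
                        "target_radius_mm")
        if len(m) == 0 or len(m) != len(i):
            continue
        rows.append({"comparison": "deviation_micc_lower", "group": label,
                     **wilcoxon_signed_rank(m["deviation_deg"].to_numpy(),
                                            i["deviation_deg"].to_numpy(),
                                            "less")})
        rows.append({"comparison": "volume_micc_larger", "group": label,
                     **wilcoxon_signed_rank(m["volume_mm3"].to_numpy(),
                                            i["volume_mm3"].to_numpy(),
                                            "greater")})
    for r in sorted(results["target_radius_mm"].dropna().unique()):
        m = results[(results["paradigm"] == "micc")
                    & (results["target_radius_mm"] == r)].sort_values("distribution")
        i = results[(results["paradigm"] == "interleaving")
                    & (results["target_radius_mm"] == r)].sort_values("distribution")
        if len(m) == 0 or len(m) != len(i):
            continue
        for col, name in [("amplitude_mA", "amplitude_micc_lower"),
                          ("current_uA", "current_micc_lower")]:
            rows.append({"comparison": name, "group": f"{r:.2f}",
                         **wilcoxon_signed_rank(m[col].to_numpy(),
                                                i[col].to_numpy(), "less")})
    return pd.DataFrame(rows)


def headline_summaries(results: pd.DataFrame) -> dict:
    """Grand summaries across all radius x fractionalization cells, reported
    both pooled over the 45 cells and as medians of per-fractionalization
    medians."""
    m = results[results["paradigm"] == "micc"]
    i = results[results["paradigm"] == "interleaving"]
    merged = m.merge(i, on=["distribution", "target_radius_mm"],
                     suffixes=("_micc", "_int"))
    out: dict = {}
    out["deviation_micc_deg"] = summarize_median_iqr(
        m["deviation_deg"].dropna())
    out["deviation_interleaving_deg"] = summarize_median_iqr(
        i["deviation_deg"].dropna())
    amp_rel = 100.0 * (merged["amplitude_mA_int"] - merged["amplitude_mA_micc"]) \
        / merged["amplitude_mA_int"]
    cur_rel = 100.0 * (merged["current_uA_int"] - merged["current_uA_micc"]) \
        / merged["current_uA_int"]
    out["amplitude_micc_lower_pct"] = summarize_median_iqr(amp_rel.dropna())
    out["current_micc_lower_pct"] = summarize_median_iqr(cur_rel.dropna())
    # medians-of-medians pooling
    med_by_frac = merged.groupby("distribution").apply(
        lambda g: pd.Series({
            "dev_micc": g["deviation_deg_micc"].median(),
            "dev_int": g["deviation_deg_int"].median()}),
        include_groups=False)
    out["deviation_micc_median_of_medians"] = float(
        med_by_frac["dev_micc"].median())
    out["deviation_interleaving_median_of_medians"] = float(
        med_by_frac["dev_int"].median())
    return out
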