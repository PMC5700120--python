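"""The three cohort-level case studies.

1. Accuracy of clinical PWV estimators (foot-to-foot along the aorta,
   the three loop methods and sum-of-squares at five analysis sites)
   against the exact theoretical wave speeds of each virtual subject.
2. Validation of the central-pressure reconstruction: the systolic
   shoulder error, epsilon = P1_algo - P1_ref, for seven PWV input
   variants.
3. The relation between augmentation index and wave reflection:
   AIx versus Pb/Pf, shoulder timing versus backward-peak timing, and
   AIx versus the network-mean bifurcation reflection coefficient.

Each ``run_case*`` accepts either a cohort directory (as written by
:func:`pulsebench.io.write_cohort`) or an in-memory list of
:class:`SubjectRecord` and returns tidy row-level DataFrames; per-subject
analysis failures are logged and counted, never fatal.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import central_pressure as cbp
from . import pwv_estimators as pwv
from . import wave_analysis as wa
from ._defaults import MMHG
from .errors import PulsebenchError, ReportError
from .virtual_cohort import SubjectRecord

__all__ = [
    "ANALYSIS_SITES",
    "CASE2_VARIANTS",
    "run_case1",
    "run_case2",
    "run_case3",
    "case3_correlations",
    "summarize_and_report",
]

logger = logging.getLogger(__name__)

# the five single-site analysis locations of case 1
ANALYSIS_SITES = ("ascending_aorta", "thoracic_aorta",
                  "abdominal_aorta_distal", "carotid", "iliac")

# the seven stiffness inputs of case 2 (plus the exact-speed oracle)
CASE2_VARIANTS = ("cf_ff", "ba_ff", "ad_ff", "dt_ff", "lndu", "qa", "sos")


def _load(cohort) -> list[SubjectRecord]:
    if isinstance(cohort, (str, Path)):
        from .io import read_cohort
        return read_cohort(cohort)
    return list(cohort)


def _stiffness_stratum(c_el: np.ndarray) -> np.ndarray:
    """Tertile labels of the elastic stiffness scale (low/mid/high)."""
    t1, t2 = np.quantile(c_el, [1 / 3, 2 / 3])
    return np.where(c_el <= t1, "low", np.where(c_el <= t2, "mid", "high"))


# --------------------------------------------------------------------------
# case 1: PWV estimator accuracy
# --------------------------------------------------------------------------

def run_case1(cohort, sites=ANALYSIS_SITES,
              methods=("ff_pressure", "ff_flow", "PU", "QA", "lnDU", "sos"),
              ) -> pd.DataFrame:
    """PWV estimates and relative errors for every subject/site/method.

    Foot-to-foot methods run along the aorta (aortic root to the
    aorto-iliac bifurcation); loop and sum-of-squares methods run at each
    analysis site against the local theoretical speed.
    """
    records = _load(cohort)
    rows = []
    for rec in records:
        wf = rec.waveforms
        fs = wf.sampling_rate
        rho = rec.parameters.blood_density
        pl = rec.network.path_lengths
        base = {"subject_id": rec.subject_id,
                "c_el_factor": rec.parameters.c_el_factor}

        if {"ff_pressure", "ff_flow"} & set(methods):
            dl = pl["abdominal_aorta_distal"] - pl["aortic_root"]
            th_path = pwv.path_theoretical_pwv(
                rec.network, "aortic_root", "abdominal_aorta_distal", rho)
            for method, getter in (("ff_pressure", wf.pressure),
                                   ("ff_flow", wf.flow)):
                if method not in methods:
                    continue
                try:
                    est = pwv.foot_to_foot_pwv(
                        getter("aortic_root"), getter("abdominal_aorta_distal"),
                        dl, fs, method=f"foot_to_foot_{method[3:]}",
                        site_or_path="aorta", theoretical=th_path)
                    rows.append({**base, "site": "aorta", "method": method,
                                 "value": est.value, "theoretical": th_path,
                                 "rel_err_pct": 100 * est.relative_error})
                except PulsebenchError as exc:
                    logger.warning("%s %s: %s", rec.subject_id, method, exc)
                    rows.append({**base, "site": "aorta", "method": method,
                                 "value": np.nan, "theoretical": th_path,
                                 "rel_err_pct": np.nan})

        for site in sites:
            if site not in wf.sites:
                logger.warning("%s: site %s missing, skipped", rec.subject_id,
                               site)
                continue
            th = rec.theoretical_pwv[site]
            P, Q, A = wf.pressure(site), wf.flow(site), wf.area(site)
            U, D = wf.velocity(site), wf.diameter(site)
            todo = []
            if "PU" in methods:
                todo.append(("PU", lambda: pwv.loop_pwv(
                    "PU", P, U, rho, fs, site, th)))
            if "QA" in methods:
                todo.append(("QA", lambda: pwv.loop_pwv(
                    "QA", Q, A, rho, fs, site, th)))
            if "lnDU" in methods:
                todo.append(("lnDU", lambda: pwv.loop_pwv(
                    "lnDU", D, U, rho, fs, site, th)))
            if "sos" in methods:
                todo.append(("sos", lambda: pwv.sum_of_squares_pwv(
                    P, U, rho, fs, site, th)))
            for method, call in todo:
                try:
                    est = call()
                    value, err = est.value, 100 * est.relative_error
                except PulsebenchError as exc:
                    logger.warning("%s %s@%s: %s", rec.subject_id, method,
                                   site, exc)
                    value, err = np.nan, np.nan
                rows.append({**base, "site": site, "method": method,
                             "value": value, "theoretical": th,
                             "rel_err_pct": err})

    df = pd.DataFrame(rows)
    if not df.empty:
        strata = {rec.subject_id: s for rec, s in zip(
            records, _stiffness_stratum(
                np.array([r.parameters.c_el_factor for r in records])))}
        df["stiffness_stratum"] = df["subject_id"].map(strata)
    return df


# --------------------------------------------------------------------------
# case 2: central-pressure validation
# --------------------------------------------------------------------------

def _case2_pwv(rec: SubjectRecord, variant: str) -> float:
    """The aortic-stiffness input of one variant, in m/s."""
    wf = rec.waveforms
    fs = wf.sampling_rate
    rho = rec.parameters.blood_density
    pl = rec.network.path_lengths

    def ff(kind, a, b):
        getter = wf.pressure if kind == "p" else wf.flow
        return pwv.foot_to_foot_pwv(getter(a), getter(b), pl[b] - pl[a],
                                    fs, site_or_path=f"{a}->{b}").value

    site = "ascending_aorta"
    if variant == "cf_ff":
        return ff("p", "carotid", "femoral")
    if variant == "ba_ff":
        return ff("p", "brachial", "ankle")
    if variant == "ad_ff":
        return ff("q", "ascending_aorta", "descending_aorta")
    if variant == "dt_ff":
        return ff("q", "descending_aorta", "thoracic_aorta")
    if variant == "lndu":
        return pwv.loop_pwv("lnDU", wf.diameter(site), wf.velocity(site),
                            rho, fs).value
    if variant == "qa":
        return pwv.loop_pwv("QA", wf.flow(site), wf.area(site),
                            rho, fs).value
    if variant == "sos":
        return pwv.sum_of_squares_pwv(wf.pressure(site), wf.velocity(site),
                                      rho, fs).value
    if variant == "true":
        return rec.theoretical_pwv[site]
    raise PulsebenchError(f"unknown case-2 PWV variant {variant!r}")


def run_case2(cohort, pwv_variants=CASE2_VARIANTS) -> pd.DataFrame:
    """Shoulder-pressure error of the reconstruction per subject/variant."""
    records = _load(cohort)
    rows = []
    for rec in records:
        wf = rec.waveforms
        fs = wf.sampling_rate
        rho = rec.parameters.blood_density
        try:
            brachial_p = wf.pressure("brachial")
            map_pa, dbp_pa = cbp.brachial_calibration(brachial_p)
            tau = cbp.fit_diastolic_decay(brachial_p, fs)
            u_root = wf.velocity("aortic_root")
            p_ref_wave = wf.pressure("aortic_root")
        except (KeyError, PulsebenchError) as exc:
            logger.warning("%s: calibration failed: %s", rec.subject_id, exc)
            continue
        for variant in pwv_variants:
            try:
                speed = _case2_pwv(rec, variant)
                recon = cbp.reconstruct_central_pressure(cbp.CBPInputs(
                    U=u_root, pwv_value=speed, MAP=map_pa, DBP=dbp_pa,
                    tau=tau, sampling_rate=fs, rho=rho))
                res = cbp.p1_error(recon, p_ref_wave, fs)
                rows.append({"subject_id": rec.subject_id, "variant": variant,
                             "pwv_value": speed,
                             "P1_algo_mmhg": res.P1_algo / MMHG,
                             "P1_ref_mmhg": res.P1_ref / MMHG,
                             "epsilon_mmhg": res.epsilon_mmhg})
            except PulsebenchError as exc:
                logger.warning("%s case2 %s: %s", rec.subject_id, variant, exc)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# case 3: augmentation index vs reflection
# --------------------------------------------------------------------------

def run_case3(cohort, sites=("ascending_aorta", "carotid")) -> pd.DataFrame:
    """AIx, wave-separation descriptors and mean reflection coefficient."""
    records = _load(cohort)
    rows = []
    for rec in records:
        wf = rec.waveforms
        fs = wf.sampling_rate
        rho = rec.parameters.blood_density
        try:
            rt_mean = pwv.mean_reflection_coefficient(rec.network, rho)
        except PulsebenchError as exc:
            logger.warning("%s: Rt mean failed: %s", rec.subject_id, exc)
            rt_mean = np.nan
        for site in sites:
            try:
                aix = wa.augmentation_index(wf.pressure(site), fs)
                sep = wa.wave_separation(wf.pressure(site), wf.velocity(site),
                                         rho, rec.theoretical_pwv[site], fs)
                rows.append({
                    "subject_id": rec.subject_id, "site": site,
                    "AIx": aix.AIx,
                    "shoulder_time_s": aix.shoulder_time,
                    "P1_mmhg": aix.shoulder_pressure / MMHG,
                    "Pb_over_Pf": sep.Pb_over_Pf,
                    "backward_peak_time_s": sep.backward_peak_time,
                    "Rt_mean": rt_mean,
                })
            except PulsebenchError as exc:
                logger.warning("%s case3 %s: %s", rec.subject_id, site, exc)
    return pd.DataFrame(rows)


def _pearson(x: pd.Series, y: pd.Series) -> float:
    mask = x.notna() & y.notna()
    x, y = x[mask], y[mask]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        logger.warning("degenerate variance: Pearson r undefined")
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def case3_correlations(rows: pd.DataFrame) -> pd.DataFrame:
    """Pearson r per site for the three reflection pairings."""
    out = []
    for site, grp in rows.groupby("site"):
        out.append({
            "site": site,
            "r_aix_pbpf": _pearson(grp["AIx"], grp["Pb_over_Pf"]),
            "r_shoulder_backward_timing": _pearson(
                grp["shoulder_time_s"], grp["backward_peak_time_s"]),
            "r_aix_rtmean": _pearson(grp["AIx"], grp["Rt_mean"]),
            "n": len(grp),
        })
    return pd.DataFrame(out)


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------

def _quartiles(s: pd.Series) -> dict:
    s = s.dropna()
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    return {"mean": float(s.mean()), "sd": float(s.std(ddof=1)),
            "q1": float(q1), "median": float(med), "q3": float(q3),
            "min": float(s.min()), "max": float(s.max()), "n": int(s.size)}


def summarize_and_report(case1_rows: pd.DataFrame | None = None,
                         case2_rows: pd.DataFrame | None = None,
                         case3_rows: pd.DataFrame | None = None,
                         out_dir: str | Path | None = None,
                         plots: bool = False) -> dict:
    """Aggregate row-level results into the summary dict; optionally write
    CSV/JSON (and PNG figures) under ``out_dir``."""
    if all(df is None or df.empty for df in (case1_rows, case2_rows,
                                             case3_rows)):
        raise ReportError("no case-study rows to summarize")
    summary: dict = {}
    if case1_rows is not None and not case1_rows.empty:
        c1 = {}
        for (site, method), grp in case1_rows.groupby(["site", "method"]):
            c1[f"{site}/{method}"] = _quartiles(grp["rel_err_pct"])
        strata = {}
        aorta_ff = case1_rows[(case1_rows["site"] == "aorta")
                              & (case1_rows["method"] == "ff_pressure")]
        for stratum, grp in aorta_ff.groupby("stiffness_stratum"):
            strata[stratum] = _quartiles(grp["rel_err_pct"])
        c1["aorta_ff_pressure_by_stratum"] = strata
        summary["case1_rel_err_pct"] = c1
    if case2_rows is not None and not case2_rows.empty:
        summary["case2_epsilon_mmhg"] = {
            variant: _quartiles(grp["epsilon_mmhg"])
            for variant, grp in case2_rows.groupby("variant")}
    if case3_rows is not None and not case3_rows.empty:
        summary["case3"] = {
            "correlations": case3_correlations(case3_rows)
            .set_index("site").to_dict(orient="index"),
            "AIx": {site: _quartiles(grp["AIx"])
                    for site, grp in case3_rows.groupby("site")},
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in (("case1_rows", case1_rows), ("case2_rows", case2_rows),
                         ("case3_rows", case3_rows)):
            if df is not None and not df.empty:
                df.to_csv(out_dir / f"{name}.csv", index=False,
                          float_format="%.10g")
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        if plots:
            _write_plots(case1_rows, case2_rows, case3_rows, out_dir)
    return summary


def _write_plots(case1_rows, case2_rows, case3_rows, out_dir: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if case1_rows is not None and not case1_rows.empty:
        sites = [s for s in case1_rows["site"].unique() if s != "aorta"]
        fig, axes = plt.subplots(1, max(len(sites), 1),
                                 figsize=(3.2 * len(sites), 3.2), squeeze=False)
        for ax, site in zip(axes[0], sites):
            grp = case1_rows[case1_rows["site"] == site]
            for method, sub in grp.groupby("method"):
                ax.scatter(sub["theoretical"], sub["value"], s=8, label=method)
            lim = [grp["theoretical"].min() * 0.8, grp["theoretical"].max() * 1.3]
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.set_title(site, fontsize=8)
            ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out_dir / "case1_identity.png", dpi=120)
        plt.close(fig)
    if case2_rows is not None and not case2_rows.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        order = [v for v in CASE2_VARIANTS
                 if v in set(case2_rows["variant"])]
        data = [case2_rows.loc[case2_rows["variant"] == v, "epsilon_mmhg"]
                .dropna() for v in order]
        ax.boxplot(data, tick_labels=order, whis=1.5)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("epsilon (mmHg)")
        fig.tight_layout()
        fig.savefig(out_dir / "case2_epsilon_box.png", dpi=120)
        plt.close(fig)
    if case3_rows is not None and not case3_rows.empty:
        pairs = [("Pb_over_Pf", "AIx"), ("backward_peak_time_s",
                                         "shoulder_time_s"), ("Rt_mean", "AIx")]
        fig, axes = plt.subplots(2, 3, figsize=(10, 6))
        for i, (site, grp) in enumerate(case3_rows.groupby("site")):
            for j, (x, y) in enumerate(pairs):
                ax = axes[i % 2, j]
                ax.scatter(grp[x], grp[y], s=8)
                ax.set_xlabel(x, fontsize=7)
                ax.set_ylabel(y, fontsize=7)
                ax.set_title(site, fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "case3_correlations.png", dpi=120)
        plt.close(fig)
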