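"""Group comparisons and the reporting layer.

Comparisons are two-tailed throughout.  Continuous per-item variables
(diameters, lengths, distances) are compared with Student's t,
Mann-Whitney, Kolmogorov-Smirnov or Kruskal-Wallis tests on pooled items;
frequency data use the chi-square test.  For fractions, the sem is
computed between synaptosome means, and pooled versus per-synaptosome
modes are always reported side by side, never silently substituted.  No
multiple-testing correction is applied (comparisons are planned and
orthogonal); all comparisons are listed so users may correct downstream.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

TESTS = ("t", "mann_whitney", "ks", "chi2", "kruskal")


@dataclass
class GroupComparison:
    variable: str
    groups: tuple[str, str]
    test: str
    statistic: float
    p_value: float  # two-tailed
    pooling: str  # "pooled" | "per_synaptosome"
    n: tuple[int, int]
    note: str = ""

    @property
    def stars(self) -> str:
        """Significance stars: p < 0.05 (*), < 0.01 (**), < 0.001 (***)."""
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value < thr:
                return s
        return "ns"


def compare(group_a, group_b, test: str = "t", pooling: str = "pooled",
            variable: str = "", names: tuple[str, str] = ("A", "B")
            ) -> GroupComparison:
    """Two-tailed comparison of two groups.

    ``group_a``/``group_b`` are 1-D samples for the continuous tests, or
    count rows of a contingency table for ``chi2``.  Degenerate
    (all-identical) inputs return statistic 0 and p = 1 with a warning
    note rather than crashing.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    note = ""
    if test == "chi2":
        table = np.vstack([a, b])
        if np.all(table == table[0, 0]) or np.any(table.sum(axis=0) == 0):
            stat, p = 0.0, 1.0
            note = "homogeneous table"
        else:
            stat, p, _, _ = sps.chi2_contingency(table)
        n = (int(a.sum()), int(b.sum()))
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 observations per group")
        n = (len(a), len(b))
        degenerate = (np.std(a) == 0 and np.std(b) == 0
                      and np.mean(a) == np.mean(b))
        if degenerate:
            stat, p = 0.0, 1.0
            note = "degenerate: all observations identical"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if test == "t":
                    stat, p = sps.ttest_ind(a, b)
                elif test == "mann_whitney":
                    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
                elif test == "ks":
                    stat, p = sps.ks_2samp(a, b)
                elif test == "kruskal":
                    stat, p = sps.kruskal(a, b)
            if math.isnan(p):
                stat, p = 0.0, 1.0
                note = "degenerate input"
    return GroupComparison(variable=variable, groups=names, test=test,
                           statistic=float(stat), p_value=float(p),
                           pooling=pooling, n=n, note=note)


def fraction_sem(per_synaptosome_fractions) -> tuple[float, float]:
    """Mean fraction and sem between synaptosome means."""
    f = np.asarray(per_synaptosome_fractions, float)
    f = f[~np.isnan(f)]
    if f.size == 0:
        return math.nan, math.nan
    sem = float(np.std(f, ddof=1) / math.sqrt(f.size)) if f.size > 1 else math.nan
    return float(f.mean()), sem


def proportion(k: int, n: int) -> tuple[float, str]:
    """Percentage 100 k/n at full precision plus the rounded display form.

    (18, 49) -> (36.73, "37%"); (64, 103) -> (62.14, "62%").
    """
    if n <= 0:
        raise ValueError(f"denominator must be positive, got {n}")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    pct = 100.0 * k / n
    return pct, f"{round(pct):.0f}%"


def build_report(dataset: dict, out_dir=None, make_figures: bool = False) -> dict:
    """Assemble the per-population summary report.

    ``dataset`` maps population tag -> list of per-scene analysis dicts
    (as produced by :func:`synaptomet.pipeline.analyze_scene`).  Returns a
    JSON-serializable report; byte-identical for identical inputs.  With
    ``out_dir`` the JSON (and optional matplotlib panels) are written out.
    """
    report: dict = {"populations": {}, "comparisons": []}
    for pop in sorted(dataset):
        scenes = dataset[pop]
        if not scenes:
            report["populations"][pop] = {"note": "no data"}
            continue
        diam = _pool(scenes, "diameters_nm")
        wad = _pool(scenes, "wadell")
        tl = _pool(scenes, "tether_lengths_nm")
        cl = _pool(scenes, "connector_lengths_nm")
        fr_teth = [s["tallies"]["fraction_tethered"] for s in scenes]
        fr_conn = [s["tallies"]["fraction_connected_all"] for s in scenes]
        mean_t, sem_t = fraction_sem(fr_teth)
        mean_c, sem_c = fraction_sem(fr_conn)
        report["populations"][pop] = {
            "n_synaptosomes": len(scenes),
            "n_vesicles": len(diam),
            "diameter_nm": _ms(diam),
            "wadell": _ms(wad),
            "density_um3": _ms([s["summary"]["vesicle_density"]
                                for s in scenes]),
            "max_extension_nm": _ms([s["summary"]["max_extension"]
                                     for s in scenes]),
            "tether_length_nm": _ms(tl),
            "connector_length_nm": _ms(cl),
            "fraction_tethered": {"pooled": _pooled_fraction(scenes,
                                                            "fraction_tethered"),
                                  "per_synaptosome_mean": mean_t,
                                  "sem_between_synaptosomes": sem_t},
            "fraction_connected": {"pooled": _pooled_fraction(
                scenes, "fraction_connected_all"),
                "per_synaptosome_mean": mean_c,
                "sem_between_synaptosomes": sem_c},
        }
    pops = sorted(dataset)
    if len(pops) == 2 and all(dataset[p] for p in pops):
        a, b = pops
        da, db = _pool(dataset[a], "diameters_nm"), _pool(dataset[b],
                                                          "diameters_nm")
        if len(da) >= 2 and len(db) >= 2:
            report["comparisons"].append(asdict(compare(
                da, db, "t", "pooled", "diameter_nm", (a, b))))
            wa, wb = _pool(dataset[a], "wadell"), _pool(dataset[b], "wadell")
            report["comparisons"].append(asdict(compare(
                wa, wb, "ks", "pooled", "wadell", (a, b))))
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n")
        if make_figures:
            _figures(dataset, out)
    return report


def _pool(scenes, key):
    out = []
    for s in scenes:
        out.extend(s.get(key, []))
    return out


def _pooled_fraction(scenes, key):
    num = sum(round(s["tallies"][key] * s["tallies"]["n_proximal"])
              if key == "fraction_tethered"
              else round(s["tallies"][key] * s["tallies"]["n_vesicles"])
              for s in scenes)
    den = sum(s["tallies"]["n_proximal"] if key == "fraction_tethered"
              else s["tallies"]["n_vesicles"] for s in scenes)
    return num / den if den else math.nan


def _ms(values) -> dict:
    v = np.asarray([x for x in values if not (isinstance(x, float)
                                              and math.isnan(x))], float)
    if v.size == 0:
        return {"mean": math.nan, "sd": math.nan, "n": 0}
    return {"mean": float(v.mean()), "sd": float(v.std(ddof=1))
            if v.size > 1 else 0.0, "n": int(v.size)}


def _figures(dataset, out_dir):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for pop in sorted(dataset):
        diam = _pool(dataset[pop], "diameters_nm")
        wad = sorted(_pool(dataset[pop], "wadell"))
        tl = _pool(dataset[pop], "tether_lengths_nm")
        if diam:
            axes[0].hist(diam, bins=20, alpha=0.5, label=pop)
        if wad:
            axes[1].plot(wad, np.linspace(0, 1, len(wad)), label=pop)
        if tl:
            axes[2].hist(tl, bins=15, alpha=0.5, label=pop)
    axes[0].set_xlabel("vesicle diameter (nm)")
    axes[1].set_xlabel("Wadell index (CDF)")
    axes[2].set_xlabel("tether length (nm)")
    for ax in axes:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(f"{out_dir}/panels.png", dpi=120)
    plt.close(fig)
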