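"""Inferential statistics (Mann-Whitney U, Pearson chi-square) and the
pipeline that ties phantom generation, probe analysis, cohort aggregation
and reporting together.

The Mann-Whitney implementation switches between an exact null distribution
(full enumeration of rank assignments, tie-aware) when both groups have at
most ``EXACT_MAX_N`` observations, and a tie-corrected, continuity-corrected
normal approximation otherwise.  Chi-square is the plain Pearson statistic
without Yates correction by default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .cohort_profiles import aggregate_profiles, summarize_cohort
from .corridor_probe import (
    AnalysisConfig,
    assess_accessibility,
    result_record,
    sample_bore_probe,
    write_results_json,
)
from .phantom_gen import CohortSpec, make_phantom, sample_cohort

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "pearson_chi_square",
    "run_pipeline",
    "EXACT_MAX_N",
]

logger = logging.getLogger(__name__)

EXACT_MAX_N = 8
ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    alpha: float = ALPHA_DEFAULT

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _u_from_ranks(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    r_a = float(ranks_a.sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0
    return u_a


def mann_whitney_u(a, b, alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    Exact when both samples have <= 8 observations: the full null
    distribution of U is enumerated over all assignments of the pooled
    (midrank-tied) ranks, and the two-sided p-value is
    P(|U - mn/2| >= |u_obs - mn/2|).  Larger samples use the tie-corrected
    normal approximation with a 0.5 continuity correction.  The reported
    statistic is min(U_a, U_b), the SPSS convention.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_a = _u_from_ranks(ranks[:n_a], n_a, n_b)
    u_b = n_a * n_b - u_a
    u_min = min(u_a, u_b)
    mu = n_a * n_b / 2.0

    if n_a <= EXACT_MAX_N and n_b <= EXACT_MAX_N:
        # enumerate every way the pooled ranks split into group a
        dev_obs = abs(u_a - mu)
        count = 0
        total = comb(n_a + n_b, n_a)
        for idx in combinations(range(n_a + n_b), n_a):
            u = _u_from_ranks(ranks[list(idx)], n_a, n_b)
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        p = count / total
        return TestResult(statistic=u_min, p_value=min(p, 1.0),
                          method="mann-whitney-u-exact", n=(n_a, n_b), alpha=alpha)

    # tie-corrected normal approximation
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        p = 1.0  # every observation tied with every other
    else:
        z = max(abs(u_a - mu) - 0.5, 0.0) / np.sqrt(var)
        p = min(2.0 * sps.norm.sf(z), 1.0)
    return TestResult(statistic=u_min, p_value=p,
                      method="mann-whitney-u-normal", n=(n_a, n_b), alpha=alpha)


def pearson_chi_square(table, yates: bool = False,
                       alpha: float = ALPHA_DEFAULT) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    Statistic: sum over cells of (O - E)^2 / E with E from the margins,
    df = (r-1)(c-1).  ``yates`` applies the continuity correction
    (2x2 tables only).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("all row and column margins must be positive")
    total = obs.sum()
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    method = "pearson-chi-square" + ("-yates" if yates else "")
    return TestResult(statistic=stat, p_value=p, method=method,
                      n=tuple(int(v) for v in row), alpha=alpha)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _config_hash(*objects) -> str:
    blob = json.dumps([_jsonable(o) for o in objects], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    try:
        return asdict(obj)
    except TypeError:
        return obj


def _test_result_dict(tr: TestResult) -> dict:
    d = asdict(tr)
    d["n"] = list(tr.n)
    d["significant"] = tr.significant
    return d


def run_pipeline(cohort: CohortSpec, cfg: AnalysisConfig, out_dir,
                 write_stations: bool = False) -> dict:
    """End-to-end synthetic run: sample a cohort, voxelize and probe every
    phantom, aggregate, test, and write the report bundle to ``out_dir``.

    Outputs (all deterministic given the cohort's master seed):
    results.json, results.csv, table1_lengths.csv, table2_groups.csv,
    mean_profile.csv, stats.json, report.md, provenance.json.
    Individual specimen failures are recorded in the report, not raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    members = sample_cohort(cohort)

    records, rows, profiles, failures = [], [], [], []
    for spec, cov in members:
        try:
            phantom = make_phantom(spec, probe_radius_mm=cfg.probe_radius_mm)
            lm = dataclasses.replace(phantom.landmarks,
                                     specimen_id=cov["specimen_id"], side=cov["side"])
            profile = sample_bore_probe(phantom.volume, lm, cfg)
            result = assess_accessibility(profile, regions=phantom.regions, landmarks=lm)
        except Exception as exc:  # specimen-level failure: record and move on
            logger.error("specimen %s failed: %s", cov["specimen_id"], exc)
            failures.append({"specimen_id": cov["specimen_id"], "error": str(exc)})
            continue
        rec = result_record(profile, result)
        rec.update(sex=cov["sex"], ethnicity=cov["ethnicity"])
        records.append(rec)
        row = {k: rec[k] for k in ("specimen_id", "side", "accessible", "length_mm",
                                   "n_events", "group")}
        row.update(sex=cov["sex"], ethnicity=cov["ethnicity"],
                   expected_accessible=phantom.ground_truth.accessible_expected)
        rows.append(row)
        if result.accessible:
            profiles.append(profile)

    if not rows:
        raise RuntimeError("no specimen could be analyzed")

    df = pd.DataFrame(rows).sort_values(["specimen_id", "side"], kind="stable")
    summary = summarize_cohort(df)

    tests: dict[str, dict] = {}
    acc_df = df[df["accessible"]]
    sexes = sorted(df["sex"].unique())
    if len(sexes) == 2:
        a = acc_df.loc[acc_df["sex"] == sexes[0], "length_mm"].to_numpy(float)
        b = acc_df.loc[acc_df["sex"] == sexes[1], "length_mm"].to_numpy(float)
        if a.size and b.size:
            tests["length_by_sex"] = _test_result_dict(mann_whitney_u(a, b))
        ct = pd.crosstab(df["sex"], df["accessible"]).to_numpy()
        if ct.shape == (2, 2) and np.all(ct.sum(axis=0) > 0) and np.all(ct.sum(axis=1) > 0):
            tests["accessibility_by_sex"] = _test_result_dict(pearson_chi_square(ct))
    eths = sorted(df["ethnicity"].unique())
    if len(eths) == 2:
        a = acc_df.loc[acc_df["ethnicity"] == eths[0], "length_mm"].to_numpy(float)
        b = acc_df.loc[acc_df["ethnicity"] == eths[1], "length_mm"].to_numpy(float)
        if a.size and b.size:
            tests["length_by_ethnicity"] = _test_result_dict(mann_whitney_u(a, b))

    # outputs
    if write_stations:
        write_results_json(records, out / "results.json")
    else:
        slim = [{k: v for k, v in r.items() if k != "stations"} for r in records]
        write_results_json(slim, out / "results.json")
    df.to_csv(out / "results.csv", index=False)
    summary.table1_frame().to_csv(out / "table1_lengths.csv", index=False)
    summary.table2_frame().to_csv(out / "table2_groups.csv", index=False)
    if profiles:
        mean_profile = aggregate_profiles(profiles)
        mean_profile.to_frame().to_csv(out / "mean_profile.csv", index=False)
    (out / "stats.json").write_text(json.dumps(tests, indent=1, sort_keys=True) + "\n")

    provenance = {
        "version": __version__,
        "config_hash": _config_hash(cohort, cfg),
        "master_seed": cohort.master_seed,
        "n_specimens": cohort.n_specimens,
        "n_analyzed": len(rows),
        "n_failures": len(failures),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")

    _write_report_md(out, summary, tests, failures, provenance)
    return {
        "summary": summary,
        "tests": tests,
        "results": df,
        "failures": failures,
        "provenance": provenance,
    }


def _write_report_md(out: Path, summary, tests: dict, failures: list,
                     provenance: dict) -> None:
    lines = ["# Corridor feasibility report", ""]
    t = summary.total
    rate = t.accessibility_rate
    lines.append(f"Specimens analyzed: {t.n}; accessible: {t.n_accessible}"
                 + (f" ({rate * 100:.1f}%)" if rate is not None else ""))
    lines.append("")
    lines.append("## Length summary (accessible specimens)")
    lines.append("")
    lines.append(summary.table1_frame().to_string(index=False))
    lines.append("")
    lines.append("## Perforation groups (excluded specimens)")
    lines.append("")
    t2 = summary.table2_frame()
    lines.append(t2.to_string(index=False) if len(t2) else "(none excluded)")
    lines.append("")
    lines.append("## Tests")
    lines.append("")
    if tests:
        for name, tr in sorted(tests.items()):
            verdict = "significant" if tr["significant"] else "not significant"
            lines.append(f"- {name}: {tr['method']} statistic={tr['statistic']:.4g}, "
                         f"p={tr['p_value']:.4g} ({verdict} at alpha={tr['alpha']})")
    else:
        lines.append("(no tests applicable)")
    if failures:
        lines.append("")
        lines.append("## Failures")
        lines.append("")
        for f in failures:
            lines.append(f"- {f['specimen_id']}: {f['error']}")
    lines.append("")
    lines.append(f"provenance: version={provenance['version']} "
                 f"config_hash={provenance['config_hash']} seed={provenance['master_seed']}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
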