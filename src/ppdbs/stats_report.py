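"""Exact small-sample statistics, bundled reference-table summaries,
and end-to-end pipeline orchestration.

The r x c exact test (Freeman-Halton extension of Fisher's test) is
computed by full enumeration of margin-fixed tables, which is the right
trade at the table sizes this package deals with (totals of a few
dozen); a seeded Monte Carlo fallback handles anything larger.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from math import lgamma
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import features as feat
from . import preprocess as prep
from . import spectral
from .core_io import FeatureTable, export_table
from .simulate import SimConfig, synthesize_session

logger = logging.getLogger("ppdbs")

ENUMERATION_CAP = 50
_TIE_REL_TOL = 1e-12


class StatsError(ValueError):
    pass


@dataclass
class ContingencyTable:
    rows: list[str]
    cols: list[str]
    counts: np.ndarray  # shape (len(rows), len(cols)), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.rows), len(self.cols)):
            raise StatsError("counts shape does not match row/col labels")
        if len(self.rows) < 2 or len(self.cols) < 2:
            raise StatsError("need at least 2 rows and 2 cols")
        if (self.counts < 0).any():
            raise StatsError("counts must be non-negative")


@dataclass
class PairedScores:
    ids: list[str]
    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if not (len(self.ids) == len(self.pre) == len(self.post)):
            raise StatsError("ids/pre/post lengths differ")

    def complete(self) -> "PairedScores":
        """Drop pairs with a missing pre or post score."""
        keep = ~(np.isnan(self.pre) | np.isnan(self.post))
        return PairedScores(
            ids=[i for i, k in zip(self.ids, keep) if k],
            pre=self.pre[keep],
            post=self.post[keep],
        )


# ---------------------------------------------------------------------------
# Exact tests


def _log_table_prob(counts: np.ndarray, lr: np.ndarray, lc: np.ndarray, ln: float) -> float:
    # P(T) = (prod r_i! prod c_j!) / (N! prod n_ij!)
    return float(lr.sum() + lc.sum() - ln - sum(lgamma(v + 1) for v in counts.flat))


def _enumerate_tables(row_sums: list[int], col_sums: list[int]):
    """Yield every non-negative integer matrix with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def fill(i: int, remaining_cols: list[int], acc: list[list[int]]):
        if i == r - 1:
            if all(v >= 0 for v in remaining_cols) and sum(remaining_cols) == row_sums[i]:
                yield acc + [list(remaining_cols)]
            return
        for cells in _row_fills(row_sums[i], remaining_cols):
            rest = [rc - x for rc, x in zip(remaining_cols, cells)]
            yield from fill(i + 1, rest, acc + [list(cells)])

    def _row_fills(total: int, caps: list[int]):
        if len(caps) == 1:
            if 0 <= total <= caps[0]:
                yield (total,)
            return
        for x in range(min(total, caps[0]) + 1):
            for rest in _row_fills(total - x, caps[1:]):
                yield (x,) + rest

    yield from fill(0, list(col_sums), [])


def fisher_exact(
    tbl: ContingencyTable,
    method: str = "enumerate",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> float:
    """Freeman-Halton exact test for an r x c table.

    Enumerates all tables with the observed margins; the p-value is the
    total probability of tables no more probable than the observed one
    (relative tie tolerance 1e-12).  Tables with total > 50 must use
    ``method="monte_carlo"`` (seeded permutation null).
    """
    counts = tbl.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise StatsError("all margins must be positive")
    n = int(counts.sum())
    lr = np.array([lgamma(v + 1) for v in row_sums])
    lc = np.array([lgamma(v + 1) for v in col_sums])
    ln = lgamma(n + 1)
    lp_obs = _log_table_prob(counts, lr, lc, ln)

    if method == "enumerate":
        if n > ENUMERATION_CAP:
            raise StatsError(
                f"table total {n} exceeds enumeration cap {ENUMERATION_CAP}; "
                f"use method='monte_carlo' (seeded, {n_permutations} permutations)"
            )
        cutoff = lp_obs + math.log1p(_TIE_REL_TOL)
        p = 0.0
        for t in _enumerate_tables(row_sums.tolist(), col_sums.tolist()):
            lp = _log_table_prob(np.asarray(t), lr, lc, ln)
            if lp <= cutoff:
                p += math.exp(lp)
        return min(p, 1.0)
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        row_labels = np.repeat(np.arange(len(row_sums)), row_sums)
        col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(col_labels)
            sim = np.zeros_like(counts)
            np.add.at(sim, (row_labels, perm), 1)
            if _log_table_prob(sim, lr, lc, ln) <= lp_obs + math.log1p(_TIE_REL_TOL):
                hits += 1
        return (hits + 1) / (n_permutations + 1)
    raise StatsError(f"unknown method {method!r}")


def binomial_two_tailed(k: int, n: int, p0: float = 0.5) -> float:
    """Doubled smaller tail of Binomial(n, p0) at k, capped at 1."""
    if not 0 <= k <= n:
        raise StatsError(f"need 0 <= k <= n, got k={k}, n={n}")
    lo = stats.binom.cdf(k, n, p0)
    hi = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lo, hi)))


# ---------------------------------------------------------------------------
# Paired-score summaries


@dataclass
class PairedTSummary:
    mean_diff: float
    sd_diff: float
    t: float
    df: int
    ci_low: float
    ci_high: float
    n: int


def paired_t_summary(scores: PairedScores, ci: float = 0.95) -> PairedTSummary:
    """Paired t on (pre - post); positive mean = improvement."""
    sc = scores.complete()
    n = len(sc.pre)
    if n < 2:
        raise StatsError(f"need >=2 complete pairs, got {n}")
    d = sc.pre - sc.post
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)
    t = mean / se if se > 0 else math.inf
    df = n - 1
    q = stats.t.ppf(0.5 + ci / 2.0, df)
    return PairedTSummary(
        mean_diff=mean, sd_diff=sd, t=float(t), df=df,
        ci_low=mean - q * se, ci_high=mean + q * se, n=n,
    )


def percent_change_summary(scores: PairedScores) -> tuple[float, float]:
    """(mean, sd) of per-pair percent improvement 100*(pre - post)/pre."""
    sc = scores.complete()
    if len(sc.pre) == 0:
        raise StatsError("no complete pairs")
    if (sc.pre == 0).any():
        bad = [i for i, p in zip(sc.ids, sc.pre) if p == 0]
        raise StatsError(f"zero pre score for {bad}; percent change undefined")
    pct = 100.0 * (sc.pre - sc.post) / sc.pre
    sd = float(pct.std(ddof=1)) if len(pct) > 1 else math.nan
    return float(pct.mean()), sd


# ---------------------------------------------------------------------------
# Bundled reference tables

_MISSING = {"NA", "Absent", "absent", "na", ""}


def _data_path(name: str):
    return resources.files("ppdbs").joinpath("data", name)


def load_clinical_scores() -> pd.DataFrame:
    """Per-trajectory intraoperative clinical subscores (bundled CSV)."""
    with _data_path("clinical_scores.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("pre", "macro_stim", "percent_change"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_evoked_features() -> pd.DataFrame:
    """Per-trajectory evoked-response features (bundled CSV).

    Cells recorded as "Absent"/"NA" load as NaN.
    """
    with _data_path("evoked_features.csv").open() as fh:
        df = pd.read_csv(fh, na_values=list(_MISSING), keep_default_na=True)
    return df


def erna_presence_table(features: pd.DataFrame | None = None) -> ContingencyTable:
    """Target x {present, absent} counts of late-oscillation presence."""
    if features is None:
        features = load_evoked_features()
    rows = []
    counts = []
    for target, grp in features.groupby("target", sort=False):
        present = int(grp["erna_amp_mv"].notna().sum())
        rows.append(str(target))
        counts.append([present, len(grp) - present])
    return ContingencyTable(rows=rows, cols=["present", "absent"], counts=np.array(counts))


def feature_column_summaries(features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-column mean/SD/count over non-missing values.

    Single-value columns report SD as NaN (undefined).
    """
    if features is None:
        features = load_evoked_features()
    num = features.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise StatsError("no numeric columns in feature table")
    rows = []
    for col in num.columns:
        vals = num[col].dropna()
        rows.append(
            {
                "column": col,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else math.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("column")


def table_summaries(features: pd.DataFrame | None = None, columns: list[str] | None = None) -> pd.DataFrame:
    out = feature_column_summaries(features)
    if columns is not None:
        missing = [c for c in columns if c not in out.index]
        if missing:
            raise StatsError(f"columns absent from feature table: {missing}")
        out = out.loc[columns]
    return out


def clinical_summaries(scores: pd.DataFrame | None = None) -> dict:
    """Paired-t and percent-change summaries of the bundled clinical table."""
    if scores is None:
        scores = load_clinical_scores()
    out: dict = {}
    pd_rows = scores[scores["target"].isin(["STN", "GPi"])]
    et_rows = scores[scores["target"] == "VIM"]
    for name, rows in [("pd", pd_rows), ("et", et_rows)]:
        summ = paired_t_summary(
            PairedScores(
                ids=list(rows["id"].astype(str)),
                pre=rows["pre"].to_numpy(),
                post=rows["macro_stim"].to_numpy(),
            )
        )
        out[name] = {
            "mean_diff": summ.mean_diff,
            "sd_diff": summ.sd_diff,
            "t": summ.t,
            "df": summ.df,
            "ci": [summ.ci_low, summ.ci_high],
            "n": summ.n,
        }
    mean_pct, sd_pct = percent_change_summary(
        PairedScores(
            ids=list(scores["id"].astype(str)),
            pre=scores["pre"].to_numpy(),
            post=scores["macro_stim"].to_numpy(),
        )
    )
    out["percent_change"] = {"mean": mean_pct, "sd": sd_pct}
    return out


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class AnalysisConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    montage: str = "bipolar_rings"
    epoch_window: tuple[float, float] = (-5.0, 16.0)
    template_min_isi: float = 20.0
    fold: str = "sum"
    out_dir: str | Path = "rundir"
    run_fixture_stats: bool = True
    run_spectral: bool | None = None  # None = auto (>=3 recording channels)


def run_pipeline(config: AnalysisConfig) -> dict:
    """simulate -> preprocess -> features -> spectral -> stats.

    Writes features.csv, refractory.json, stats.json, and manifest.json
    into ``config.out_dir`` and returns the stats payload.  Deterministic
    for a fixed config (including the simulator seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulate: seed=%d", config.sim.seed)
    rec, truth = synthesize_session(config.sim)
    logger.info("simulate: %d events, %.2f s", len(rec.events), rec.duration)

    reref = prep.rereference(rec, config.montage)
    channel = reref.channels[0].label
    epochs = prep.extract_epochs(reref, window=config.epoch_window, channel=channel)
    logger.info("preprocess: %d epochs on %s", len(epochs), channel)
    composites = prep.fold_polarity(epochs, fold=config.fold)
    template = prep.build_template(composites, min_isi=config.template_min_isi)
    noise_sd = feat.estimate_noise_sd(template.waveform, template.times_ms)

    tests = [
        prep.subtract_template(c, template)
        for c in composites
        if c.pulse_role == "test" and c.isi < config.template_min_isi
    ]
    logger.info("features: %d test composites, template n=%d", len(tests), template.n_averaged)

    profile = feat.ppr_curve(tests, template, component="r1")
    erna_prof = feat.ppr_curve(tests, template, component="erna")
    profile.ppr["erna"] = erna_prof.ppr["erna"]
    profile.facilitation_isis["erna"] = erna_prof.facilitation_isis["erna"]
    arp = feat.estimate_arp(profile)
    rrp = feat.estimate_rrp(profile)

    template_feats = feat.extract_all_features(template, noise_sd)
    test_feats = {c.isi: feat.extract_all_features(c, noise_sd) for c in tests}
    shifts = feat.latency_shifts(test_feats, template_feats)

    rows = []
    for c in tests:
        f = test_feats[c.isi]
        r1, erna = f["r1"], f["erna"]
        rows.append(
            {
                "channel": c.channel,
                "isi_ms": c.isi,
                "r1_present": bool(r1.present),
                "r1_peak_lat_ms": r1.peak_lat,
                "r1_peak_amp_mv": r1.peak_amp,
                "r1_trough_lat_ms": r1.trough_lat,
                "r1_trough_amp_mv": r1.trough_amp,
                "r1_area_mv_ms": r1.area,
                "erna_present": bool(erna.present),
                "erna_peak_lat_ms": erna.peak_lat,
                "erna_peak_amp_mv": erna.peak_amp,
                "erna_area_mv_ms": erna.area,
            }
        )
    ftable = FeatureTable(
        frame=pd.DataFrame(rows).sort_values("isi_ms").reset_index(drop=True),
        key=("channel", "isi_ms"),
        units={
            "channel": "", "isi_ms": "ms", "r1_present": "", "r1_peak_lat_ms": "ms",
            "r1_peak_amp_mv": "mV", "r1_trough_lat_ms": "ms", "r1_trough_amp_mv": "mV",
            "r1_area_mv_ms": "mV*ms", "erna_present": "", "erna_peak_lat_ms": "ms",
            "erna_peak_amp_mv": "mV", "erna_area_mv_ms": "mV*ms",
        },
    )
    export_table(ftable, out / "features.csv")
    export_table(shifts, out / "latency_shifts.csv")

    refractory = {
        "channel": channel,
        "noise_sd_mv": noise_sd,
        "arp_ms": arp,
        "rrp_ms": rrp,
        "arp_run_ms": list(profile.arp_run) if profile.arp_run else None,
        "rrp_run_ms": list(profile.rrp_run) if profile.rrp_run else None,
        "isis_ms": profile.isis.tolist(),
        "ppr": {k: v.tolist() for k, v in profile.ppr.items()},
        "facilitation_isis_ms": {k: v.tolist() for k, v in profile.facilitation_isis.items()},
    }
    with open(out / "refractory.json", "w") as fh:
        json.dump(refractory, fh, indent=2, sort_keys=True)

    stats_payload: dict = {
        "seed": config.sim.seed,
        "arp_ms": arp,
        "rrp_ms": rrp,
        "n_test_composites": len(tests),
        "template_n_averaged": template.n_averaged,
    }

    do_spectral = config.run_spectral
    if do_spectral is None:
        do_spectral = config.sim.n_record_channels >= 3 and config.sim.rest_duration > 0
    if do_spectral:
        seg_rec = prep.rereference(rec, "common_average_segments")
        beta = spectral.band_power_by_channel(
            seg_rec, rest_interval=(0.0, config.sim.rest_duration)
        )
        areas = []
        for ch in seg_rec.channels:
            eps = prep.extract_epochs(seg_rec, window=config.epoch_window, channel=ch.label)
            comps = prep.fold_polarity(eps, fold=config.fold)
            tmpl_ch = prep.build_template(comps, min_isi=config.template_min_isi)
            areas.append(
                {
                    "channel": ch.label,
                    "r1_area": feat.response_area(
                        tmpl_ch.waveform, tmpl_ch.times_ms, feat.COMPONENT_WINDOWS["r1"]
                    ),
                    "erna_area": feat.response_area(
                        tmpl_ch.waveform, tmpl_ch.times_ms, feat.COMPONENT_WINDOWS["erna"]
                    ),
                }
            )
        assoc = spectral.beta_feature_association(beta, pd.DataFrame(areas))
        stats_payload["beta_association"] = assoc
        stats_payload["beta_power"] = {b.channel: b.power for b in beta}
        logger.info("spectral: %s", assoc)

    if config.run_fixture_stats:
        tbl = erna_presence_table()
        stats_payload["fixtures"] = {
            "erna_presence_fisher_p": fisher_exact(tbl),
            "concordance_binomial_p": binomial_two_tailed(6, 6),
            "clinical": clinical_summaries(),
            "feature_column_summaries": feature_column_summaries().to_dict(orient="index"),
        }

    with open(out / "stats.json", "w") as fh:
        json.dump(stats_payload, fh, indent=2, sort_keys=True)
    manifest = {
        "seed": config.sim.seed,
        "montage": config.montage,
        "epoch_window_ms": list(config.epoch_window),
        "fold": config.fold,
        "template_min_isi_ms": config.template_min_isi,
        "isi_spacing": "log",
        "n_events": len(rec.events),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: arp=%s rrp=%s", arp, rrp)
    return stats_payload


__all__ = [
    "AnalysisConfig",
    "ContingencyTable",
    "PairedScores",
    "PairedTSummary",
    "StatsError",
    "binomial_two_tailed",
    "clinical_summaries",
    "erna_presence_table",
    "feature_column_summaries",
    "fisher_exact",
    "load_clinical_scores",
    "load_evoked_features",
    "paired_t_summary",
    "percent_change_summary",
    "run_pipeline",
    "table_summaries",
]
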