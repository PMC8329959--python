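"""Orchestration of the full study replica.

``run_extract`` turns image/mask pairs into a long feature table;
``survival_analysis`` runs the inference chain on a feature table joined to
a clinical table; ``run_agreement`` computes per-feature observer agreement
from two feature tables.  Every output table is a CSV whose first line is a
provenance comment (config hash + seed), so identical config and seed give
byte-identical outputs.

The inference chain follows the exploratory-study design: texture features
are first compared between survivors and non-survivors (Mann-Whitney), and
only the features that pass that gate at ``alpha`` are dichotomized at
their ROC-optimal cutoff and carried into Kaplan-Meier / log-rank and Cox
analyses.  No multiple-testing correction is applied by default (a Holm
correction of the gate is available via config) -- a deliberate,
documented property of this design: the cutoff optimization makes the
downstream log-rank anti-conservative, which the test suite measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .config import RunConfig
from .reliability import categorize_agreement, icc
from .survival import (
    cox_fit,
    dichotomize,
    km_estimate,
    levene_test,
    logrank_test,
    mann_whitney,
    optimal_cutoff,
    spearman_matrix,
)
from .texture import FEATURE_NAMES, extract_features

logger = logging.getLogger("texsurv")

__all__ = ["SurvivalTables", "run_extract", "extract_second_reading",
           "survival_analysis", "run_survival", "run_agreement",
           "write_survival_tables"]

_IMAGE_EXTS = (".nii", ".nii.gz", ".tif", ".tiff")

# clinical univariate models: variable -> (reference level, comparison levels)
_CLINICAL_VARS: dict[str, tuple[object, list[object]]] = {
    "age_group": (">=45", ["<45"]),
    "n_stage": ("0-1", ["2-3"]),
    "m_stage": (0, [1]),
    "er": ("positive", ["negative"]),
    "pr": ("positive", ["negative"]),
    "her2": ("positive", ["negative"]),
    "subtype": ("luminal-like", ["HER2-like", "basal-like"]),
    "neoadjuvant_chemo": (0, [1]),
    "adjuvant_chemo": (0, [1]),
    "adjuvant_rt": (0, [1]),
}


def _subject_id(path: Path) -> str:
    name = path.name
    for ext in _IMAGE_EXTS:
        if name.endswith(ext):
            return name[: -len(ext)]
    return path.stem


# ---------------------------------------------------------------------------
# feature extraction


def run_extract(config: RunConfig) -> tuple[pd.DataFrame, list[dict]]:
    """Extract texture features for every image/mask pair in the config dirs.

    Subjects whose mask is missing, unreadable or incongruent are skipped
    with an error record; if every subject fails, the run fails.  Returns
    the long feature table and the exclusion records, and writes
    ``features.csv`` (plus ``exclusions.csv`` when non-empty) to the output
    directory.
    """
    image_dir = Path(config.image_dir)
    mask_dir = Path(config.mask_dir)
    out_dir = Path(config.out_dir)
    images = sorted(
        p for p in image_dir.iterdir() if p.name.endswith(_IMAGE_EXTS)
    )
    if not images:
        raise FileNotFoundError(f"no images found in {image_dir}")

    rows: list[tuple[str, object]] = []
    exclusions: list[dict] = []
    for img_path in images:
        sid = _subject_id(img_path)
        try:
            mask_path = mask_dir / img_path.name
            if not mask_path.exists():
                raise FileNotFoundError(f"no mask for {img_path.name}")
            img = tio.read_image(img_path)
            mask = tio.read_mask(mask_path)
            feats = extract_features(
                img, mask, config.scales, bin_width=config.entropy_bin_width
            )
        except Exception as exc:  # noqa: BLE001 - per-subject error accounting
            logger.error("extract: excluding %s: %s", sid, exc)
            exclusions.append({"subject_id": sid, "reason": str(exc)})
            continue
        rows.extend((sid, f) for f in feats)

    if not rows:
        raise RuntimeError("feature extraction failed for every subject")
    table = tio.features_to_frame(rows)
    tio.write_table(table, out_dir / "features.csv", config.provenance())
    if exclusions:
        tio.write_table(
            pd.DataFrame(exclusions), out_dir / "exclusions.csv", config.provenance()
        )
    logger.info(
        "extract: %d subjects, %d excluded, %d scales",
        table["subject_id"].nunique(), len(exclusions), len(config.scales),
    )
    return table, exclusions


def extract_second_reading(data_dir: str | Path, config: RunConfig) -> pd.DataFrame:
    """Re-extract features with a perturbed ROI per subject (second reader).

    Emulates an independent manual re-draw of each ROI (one-pixel contour
    changes) and returns the resulting feature table.
    """
    from .synthetic import perturb_mask

    data_dir = Path(data_dir)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1311]))
    rows: list[tuple[str, object]] = []
    for img_path in sorted((data_dir / "images").iterdir()):
        sid = _subject_id(img_path)
        img = tio.read_image(img_path)
        mask = tio.read_mask(data_dir / "masks" / img_path.name)
        mask2 = perturb_mask(mask, int(rng.integers(0, 2**31 - 1)))
        rows.extend(
            (sid, f)
            for f in extract_features(
                img, mask2, config.scales, bin_width=config.entropy_bin_width
            )
        )
    return tio.features_to_frame(rows)


# ---------------------------------------------------------------------------
# survival chain


@dataclass
class SurvivalTables:
    """All result tables of one survival run, keyed like the output files."""

    comparison: pd.DataFrame
    cutoffs: pd.DataFrame
    logrank: pd.DataFrame
    clinical_cox: pd.DataFrame
    feature_cox: pd.DataFrame
    bivariate_cox: pd.DataFrame
    spearman: pd.DataFrame
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_subjects: int = 0


def _km_frame(curve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_months": curve.timeline,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
        }
    )


def _brief(warnings_: tuple[str, ...]) -> str:
    """First line of each fit warning, for compact table notes."""
    return "; ".join(w.splitlines()[0] for w in warnings_)


def _flag_row(**kw) -> dict:
    row = {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan}
    row.update(kw)
    return row


def _univariate_clinical(merged: pd.DataFrame) -> pd.DataFrame:
    """One univariate Cox model per clinical variable (dummy-coded levels)."""
    rows: list[dict] = []
    for var, (ref, levels) in _CLINICAL_VARS.items():
        if var not in merged.columns:
            continue
        col = merged[var]
        rows.append(
            {
                "variable": var, "level": str(ref),
                "n": int((col == ref).sum()), "hr": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                "note": "reference",
            }
        )
        data = merged[["os_months", "event"]].copy()
        dummies = []
        for lv in levels:
            dummy = f"{var}={lv}"
            data[dummy] = (col == lv).astype(float)
            dummies.append((lv, dummy))
        try:
            fit = cox_fit(data, [d for _, d in dummies])
            for lv, dummy in dummies:
                lo, hi = fit.ci(dummy)
                rows.append(
                    {
                        "variable": var, "level": str(lv),
                        "n": int((col == lv).sum()), "hr": fit.hr(dummy),
                        "ci_low": lo, "ci_high": hi, "p_value": fit.p(dummy),
                        "note": _brief(fit.warnings),
                    }
                )
        except (ValueError, RuntimeError) as exc:
            logger.warning("univariate Cox for %s failed: %s", var, exc)
            for lv, _ in dummies:
                rows.append(
                    _flag_row(
                        variable=var, level=str(lv), n=int((col == lv).sum()),
                        note=f"not estimable: {exc}",
                    )
                )
    return pd.DataFrame(rows)


def survival_analysis(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
    min_overlap: float = 0.8,
) -> SurvivalTables:
    """Run the full inference chain on a feature table joined to a clinical table.

    ``features`` is the long table from :func:`run_extract` (or the
    synthetic feature generator); ``clinical`` must carry ``subject_id``,
    ``os_months`` and ``event``.  The two must share at least
    ``min_overlap`` of the feature table's subjects.
    """
    feat_ids = set(features["subject_id"])
    overlap = len(feat_ids & set(clinical["subject_id"])) / max(len(feat_ids), 1)
    if overlap < min_overlap:
        raise ValueError(
            f"only {overlap:.0%} of feature subjects have clinical records "
            f"(>= {min_overlap:.0%} required)"
        )

    comparison_rows: list[dict] = []
    cutoff_rows: list[dict] = []
    logrank_rows: list[dict] = []
    feature_cox_rows: list[dict] = []
    bivariate_rows: list[dict] = []
    spearman_rows: list[dict] = []
    km_curves: dict[str, pd.DataFrame] = {}

    n_input = clinical["subject_id"].nunique()

    for ssf, feats_at_scale in features.groupby("ssf"):
        wide = feats_at_scale.set_index("subject_id")[list(FEATURE_NAMES)]
        merged = clinical.merge(wide, on="subject_id", how="inner")
        survivors = merged["event"] == 0

        # collinearity screen at this scale
        complete = merged[list(FEATURE_NAMES)].dropna()
        if len(complete) >= 3:
            for entry in spearman_matrix(complete):
                spearman_rows.append(
                    {
                        "ssf": ssf, "feature_a": entry.feature_a,
                        "feature_b": entry.feature_b, "rho": entry.rho,
                        "p_value": entry.p_value,
                    }
                )

        # survivor / non-survivor comparison, then the alpha gate
        scale_comp: list[dict] = []
        for name in FEATURE_NAMES:
            vals = merged[name]
            ok = vals.notna()
            n_missing = int((~ok).sum())
            a = vals[ok & survivors].to_numpy()
            b = vals[ok & ~survivors].to_numpy()
            row = {
                "ssf": ssf, "feature": name,
                "n_survivors": a.size, "n_nonsurvivors": b.size,
                "n_missing": n_missing,
                "mean_survivors": a.mean() if a.size else np.nan,
                "mean_nonsurvivors": b.mean() if b.size else np.nan,
                "median_survivors": np.median(a) if a.size else np.nan,
                "median_nonsurvivors": np.median(b) if b.size else np.nan,
            }
            if a.size >= 2 and b.size >= 2:
                lev_stat, lev_p = levene_test([a, b])
                mwu = mann_whitney(a, b)
                row.update(
                    levene_stat=lev_stat, levene_p=lev_p,
                    u_statistic=mwu.u_statistic, p_value=mwu.p_value,
                    degenerate=mwu.degenerate,
                )
            else:
                row.update(
                    levene_stat=np.nan, levene_p=np.nan,
                    u_statistic=np.nan, p_value=np.nan, degenerate=True,
                )
            scale_comp.append(row)

        pvals = np.array([r["p_value"] for r in scale_comp])
        if holm:
            order = np.argsort(pvals)
            m = np.isfinite(pvals).sum()
            adjusted = np.full_like(pvals, np.nan)
            running = 0.0
            for rank, i in enumerate(order):
                if not np.isfinite(pvals[i]):
                    continue
                running = max(running, (m - rank) * pvals[i])
                adjusted[i] = min(running, 1.0)
            gate = adjusted < alpha
        else:
            gate = pvals < alpha
        for row, sig in zip(scale_comp, gate):
            row["significant"] = bool(sig)
        comparison_rows.extend(scale_comp)

        # cutoff -> dichotomy -> KM / log-rank -> Cox for gated features
        for row in scale_comp:
            if not row["significant"]:
                continue
            name = row["feature"]
            ok = merged[name].notna()
            sub = merged[ok]
            vals = sub[name].to_numpy()
            labels = sub["event"].to_numpy()
            cut = optimal_cutoff(vals, labels, feature=name)
            dich = dichotomize(vals, cut.cutoff, feature=name)
            cutoff_rows.append(
                {
                    "ssf": ssf, "feature": name, "cutoff": cut.cutoff,
                    "auc": cut.auc, "youden_j": cut.youden_j,
                    "n_low": dich.n_low, "n_high": dich.n_high,
                    "degenerate": dich.has_empty_group,
                }
            )
            if dich.has_empty_group:
                logrank_rows.append(
                    {
                        "ssf": ssf, "feature": name, "chi_square": np.nan,
                        "p_value": np.nan, "note": "empty group at cutoff",
                    }
                )
                continue

            low = dich.labels == "low"
            key = f"{name}" if ssf == 0 else f"{name}_ssf{ssf:g}"
            for grp, sel in (("low", low), ("high", ~low)):
                curve = km_estimate(
                    sub.loc[sel, "os_months"], sub.loc[sel, "event"]
                )
                km_curves[f"{key}_{grp}"] = _km_frame(curve)
            lr = logrank_test(
                sub.loc[low, "os_months"], sub.loc[low, "event"],
                sub.loc[~low, "os_months"], sub.loc[~low, "event"],
            )
            logrank_rows.append(
                {
                    "ssf": ssf, "feature": name, "chi_square": lr.chi_square,
                    "p_value": lr.p_value, "note": "",
                }
            )

            # univariate Cox on the dichotomized feature (low vs high ref)
            data = sub[["os_months", "event"]].copy()
            data["low"] = low.astype(float)
            try:
                fit = cox_fit(data, ["low"])
                lo, hi = fit.ci("low")
                feature_cox_rows.append(
                    {
                        "ssf": ssf, "feature": name, "cutoff": cut.cutoff,
                        "n_low": dich.n_low, "n_high": dich.n_high,
                        "hr": fit.hr("low"), "ci_low": lo, "ci_high": hi,
                        "p_value": fit.p("low"),
                        "note": _brief(fit.warnings),
                    }
                )
            except (ValueError, RuntimeError) as exc:
                feature_cox_rows.append(
                    _flag_row(
                        ssf=ssf, feature=name, cutoff=cut.cutoff,
                        n_low=dich.n_low, n_high=dich.n_high,
                        note=f"not estimable: {exc}",
                    )
                )

            # bivariate Cox: feature + M stage, one model per feature
            if "m_stage" in sub.columns and sub["m_stage"].nunique() > 1:
                data["m1"] = (sub["m_stage"] == 1).to_numpy(dtype=float)
                try:
                    fit = cox_fit(data, ["m1", "low"])
                    for cov, label in (("m1", "M1"), ("low", f"low {name}")):
                        lo, hi = fit.ci(cov)
                        bivariate_rows.append(
                            {
                                "ssf": ssf, "model": name, "variable": label,
                                "hr": fit.hr(cov), "ci_low": lo, "ci_high": hi,
                                "p_value": fit.p(cov),
                                "note": _brief(fit.warnings),
                            }
                        )
                except (ValueError, RuntimeError) as exc:
                    bivariate_rows.append(
                        _flag_row(
                            ssf=ssf, model=name, variable=f"low {name} + M1",
                            note=f"not estimable: {exc}",
                        )
                    )

    clinical_cox = _univariate_clinical(clinical)

    return SurvivalTables(
        comparison=pd.DataFrame(comparison_rows),
        cutoffs=pd.DataFrame(cutoff_rows),
        logrank=pd.DataFrame(logrank_rows),
        clinical_cox=clinical_cox,
        feature_cox=pd.DataFrame(feature_cox_rows),
        bivariate_cox=pd.DataFrame(bivariate_rows),
        spearman=pd.DataFrame(spearman_rows),
        km_curves=km_curves,
        n_subjects=n_input,
    )


def write_survival_tables(
    tables: SurvivalTables, out_dir: str | Path, provenance: str
) -> None:
    """Write every result table as a CSV mirroring the study's table layout."""
    out_dir = Path(out_dir)
    tio.write_table(tables.clinical_cox, out_dir / "table1_clinical_cox.csv", provenance)
    tio.write_table(tables.comparison, out_dir / "table2_feature_comparison.csv", provenance)
    tio.write_table(tables.feature_cox, out_dir / "table3_feature_cox.csv", provenance)
    tio.write_table(tables.bivariate_cox, out_dir / "table4_bivariate_cox.csv", provenance)
    tio.write_table(tables.cutoffs, out_dir / "cutoffs.csv", provenance)
    tio.write_table(tables.logrank, out_dir / "logrank.csv", provenance)
    tio.write_table(tables.spearman, out_dir / "spearman.csv", provenance)
    for key, frame in tables.km_curves.items():
        tio.write_table(frame, out_dir / f"km_{key}.csv", provenance)


def run_survival(config: RunConfig, features_csv: str | Path | None = None) -> SurvivalTables:
    """Load tables per config, run :func:`survival_analysis`, write CSVs."""
    out_dir = Path(config.out_dir)
    features = tio.read_table(features_csv or out_dir / "features.csv")
    clinical = tio.read_table(config.clinical_csv)
    tables = survival_analysis(
        features, clinical, alpha=config.alpha, holm=config.holm
    )
    write_survival_tables(tables, out_dir, config.provenance())
    return tables


# ---------------------------------------------------------------------------
# observer agreement


def run_agreement(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    form: str = "absolute",
) -> pd.DataFrame:
    """Per-feature, per-scale ICC between two feature tables.

    The tables must share at least 5 subjects (on ``subject_id`` and
    ``ssf``); each shared (subject, scale) contributes one row of the
    subjects x 2 rating matrix.
    """
    merged = features_a.merge(
        features_b, on=["subject_id", "ssf"], suffixes=("_a", "_b")
    )
    rows = []
    for ssf, sub in merged.groupby("ssf"):
        for name in FEATURE_NAMES:
            pair = sub[[f"{name}_a", f"{name}_b"]].dropna()
            if len(pair) < 5:
                raise ValueError(
                    f"fewer than 5 shared subjects for {name} at SSF {ssf:g}"
                )
            value = icc(pair.to_numpy(), form=form)
            rows.append(
                {
                    "ssf": ssf, "feature": name, "icc": value,
                    "category": categorize_agreement(value) if value is not None else "undefined",
                    "n_subjects": len(pair), "n_ratings": 2,
                }
            )
    return pd.DataFrame(rows)
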