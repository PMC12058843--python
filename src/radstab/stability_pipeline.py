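"""End-to-end inter-observer stability study: simulate, extract, agree, classify.

``run_study`` executes the whole chain at desk scale: generate phantoms,
simulate the observer panel, extract the 1,246-feature catalogue per
(nodule, observer), build per-nodule Dice agreement records, compute one
OCCC per feature (rows = nodules, columns = observers) and bin it into the
four stability classes.  The reporting helpers then reshape the result into
the study's analysis artifacts: a per-observer Dice table, a stability-class
distribution table, the Dice-versus-diameter regression, and subgroup OCCC
comparisons with Kruskal–Wallis and Bonferroni-adjusted pairwise tests.

The headline percentages of the source cohort (e.g. the share of stable
features) are properties of its private CT data; this pipeline reports the
analogous percentages for the synthetic study and never asserts equality.
"""

from __future__ import annotations

import json
import logging
import re
import time
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .agreement_stats import (
    AgreementRecord,
    agreement_record,
    classify_stability,
    estimate_diameter,
    occc,
    STABILITY_LABELS,
    STABLE_THRESHOLD,
)
from .phantom_sim import (
    StudyDesign,
    generate_phantom,
    resolve_profiles,
    sample_nodule_specs,
    simulate_observer_mask,
    _subseed,
)
from .radiomic_features import FeatureConfig, catalogue_names, extract_all, prepare_images

__all__ = [
    "StudyResult",
    "run_study",
    "stability_table",
    "dc_table",
    "dc_diameter_analysis",
    "subgroup_occc_comparison",
    "feature_metadata",
    "FEATURE_CLASSES",
]

logger = logging.getLogger("radstab")

#: the eight feature classes of the stability table, in report order
FEATURE_CLASSES = (
    "Original_firstorder",
    "Original_shape",
    "Original_GLCM",
    "Original_GLRLM",
    "Original_GLSZM",
    "Original_GLDM",
    "LoG",
    "Wavelet",
)

_FAMILY_LABEL = {
    "firstorder": "firstorder",
    "shape": "shape",
    "glcm": "GLCM",
    "glrlm": "GLRLM",
    "glszm": "GLSZM",
    "gldm": "GLDM",
}


def feature_metadata(name: str) -> dict[str, object]:
    """Parse a canonical feature name into its strata.

    Returns image_type, family, feature, the 8-way feature class, and (when
    applicable) the wavelet sub-band or LoG sigma.
    """
    image_type, family, feat = name.split("_", 2)
    meta: dict[str, object] = {
        "image_type": image_type,
        "family": family,
        "feature": feat,
        "wavelet_subband": None,
        "log_sigma_mm": None,
    }
    if image_type == "original":
        meta["feature_class"] = f"Original_{_FAMILY_LABEL[family]}"
    elif image_type.startswith("log-"):
        meta["feature_class"] = "LoG"
        meta["log_sigma_mm"] = float(re.match(r"log-sigma-([\d.]+)-mm", image_type).group(1))
    else:
        meta["feature_class"] = "Wavelet"
        meta["wavelet_subband"] = image_type.split("-", 1)[1]
    return meta


@dataclass
class StudyResult:
    """Everything a completed study produced."""

    design: StudyDesign
    config: FeatureConfig
    manifest: pd.DataFrame  # one row per nodule
    agreement: list[AgreementRecord]
    features: pd.DataFrame  # index (nodule_id, observer), 1246 columns
    occc_per_feature: pd.Series
    stability: pd.DataFrame  # feature, occc, label + metadata columns
    occc_by_type: pd.DataFrame  # feature x nodule type, OCCC within stratum
    excluded_features: list[str] = field(default_factory=list)

    @property
    def observer_ids(self) -> list[str]:
        return list(self.features.index.get_level_values("observer").unique())


def run_study(
    design: StudyDesign,
    config: FeatureConfig | None = None,
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Run the full simulated inter-observer study.

    Deterministic given ``design.master_seed``.  When ``out_dir`` is given the
    analysis tables are also written there as CSV/JSON; if a stage fails the
    tables computed so far are still persisted alongside an error manifest.
    """
    config = config or FeatureConfig()
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    try:
        result = _run_study_inner(design, config)
    except Exception as exc:
        if out_path is not None:
            (out_path / "error_manifest.json").write_text(
                json.dumps({"error": repr(exc)}, indent=2)
            )
        raise
    if out_path is not None:
        _persist(result, out_path)
    return result


def _run_study_inner(design: StudyDesign, config: FeatureConfig) -> StudyResult:
    t0 = time.time()
    profiles = resolve_profiles(design)
    logger.info("calibrated %d observer profiles in %.1fs", len(profiles), time.time() - t0)
    specs = sample_nodule_specs(design)
    obs_ids = [p.name for p in profiles]

    records: list[AgreementRecord] = []
    rows = []
    feat_rows = []
    feat_index = []
    for i, spec in enumerate(specs):
        nid = f"nodule{i:04d}"
        vol, ref = generate_phantom(spec)
        scale = design.class_jitter_scale.get(spec.nodule_type, 1.0)
        nodule_seed = _subseed(design.master_seed, "obs", i)
        masks = [
            simulate_observer_mask(ref, p, nodule_seed, jitter_scale=scale)
            for p in profiles
        ]
        rec = agreement_record(masks, obs_ids, reference_index=0, nodule_id=nid)
        records.append(rec)
        images = prepare_images(vol, config)
        for p, m in zip(profiles, masks):
            feat_rows.append(extract_all(vol, m, config, images=images))
            feat_index.append((nid, p.name))
        rows.append(
            {
                "nodule_id": nid,
                "nodule_type": spec.nodule_type,
                "true_diameter_mm": spec.diameter_mm,
                "true_diameter_cm": spec.diameter_mm / 10.0,
                "estimated_diameter_cm": estimate_diameter(ref),
                "median_dc": rec.median_dc,
            }
        )
        if (i + 1) % 10 == 0:
            logger.info("processed %d/%d nodules (%.1fs)", i + 1, len(specs), time.time() - t0)
    manifest = pd.DataFrame(rows)
    features = pd.DataFrame(
        feat_rows,
        index=pd.MultiIndex.from_tuples(feat_index, names=["nodule_id", "observer"]),
        columns=catalogue_names(config),
    )

    occc_s, excluded = _occc_over_study(features, obs_ids)
    meta = pd.DataFrame([feature_metadata(f) for f in occc_s.index], index=occc_s.index)
    stability = meta.assign(
        occc=occc_s,
        label=[classify_stability(v).label for v in occc_s],
    )
    stability.index.name = "feature"

    # per-nodule-type OCCC (Fig 7B-style stratification)
    by_type = {}
    for ntype in ("SN", "pSN", "pGGN"):
        ids = manifest.loc[manifest.nodule_type == ntype, "nodule_id"]
        if len(ids) < 2:
            continue
        sub = features.loc[features.index.get_level_values("nodule_id").isin(ids)]
        s, _ = _occc_over_study(sub, obs_ids)
        by_type[ntype] = s
    occc_by_type = pd.DataFrame(by_type)

    logger.info("study of %d nodules x %d observers done in %.1fs",
                len(specs), len(profiles), time.time() - t0)
    return StudyResult(
        design, config, manifest, records, features,
        occc_s, stability, occc_by_type, excluded,
    )


def _occc_over_study(
    features: pd.DataFrame, obs_ids: list[str]
) -> tuple[pd.Series, list[str]]:
    """One OCCC per feature: rows = nodules, columns = observers."""
    wide = features.unstack("observer")  # columns (feature, observer)
    values = {}
    excluded = []
    for feat in features.columns:
        mat = wide[feat].reindex(columns=obs_ids).to_numpy()
        if np.isnan(mat).any():
            excluded.append(feat)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values[feat] = occc(mat)
    if excluded:
        logger.warning("excluded %d features with NaN values from OCCC", len(excluded))
    return pd.Series(values, name="occc"), excluded


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def stability_table(sr: StudyResult) -> pd.DataFrame:
    """Stability-class distribution per feature class, with totals.

    One row per feature class plus a Total row; columns give the class size,
    the count (and %) per OCCC bin, the number of excluded (NaN) features and
    the good-stability rate (share of classified features with OCCC >= 0.75).
    """
    all_names = catalogue_names(sr.config)
    meta_all = pd.DataFrame([feature_metadata(f) for f in all_names], index=all_names)
    excluded = set(sr.excluded_features)
    rows = []
    for cls in FEATURE_CLASSES + ("Total",):
        if cls == "Total":
            names = list(all_names)
        else:
            names = list(meta_all.index[meta_all.feature_class == cls])
        classified = sr.stability.loc[sr.stability.index.isin(names)]
        row: dict[str, object] = {
            "feature_class": cls,
            "n_features": len(names),
            "n_excluded_nan": sum(1 for f in names if f in excluded),
        }
        n_cls = len(classified)
        for label in STABILITY_LABELS:
            cnt = int((classified.label == label).sum())
            row[f"n_{label}"] = cnt
            row[f"pct_{label}"] = 100.0 * cnt / n_cls if n_cls else float("nan")
        row["good_stability_rate_pct"] = (
            100.0 * float((classified.occc >= STABLE_THRESHOLD).mean()) if n_cls else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature_class")


def _median_iqr(x: np.ndarray) -> str:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return f"{q2:.2f} ({q3 - q1:.2f})"


def dc_table(sr: StudyResult, reference_observer: str = "A") -> pd.DataFrame:
    """Per-observer median (IQR) Dice against the reference observer.

    Columns are Total and the three nodule types; the reference row is shown
    as em-dashes; the last row holds the Kruskal–Wallis p-value across
    observers (blank when there is no variation).
    """
    obs = sr.observer_ids
    others = [o for o in obs if o != reference_observer]
    strata = {"Total": sr.manifest.nodule_id}
    for ntype in ("SN", "pSN", "pGGN"):
        strata[ntype] = sr.manifest.loc[sr.manifest.nodule_type == ntype, "nodule_id"]
    dc = {
        rec.nodule_id: rec.dc_vs_reference for rec in sr.agreement
    }
    table: dict[str, dict[str, str]] = {c: {} for c in strata}
    pvals: dict[str, str] = {}
    for col, ids in strata.items():
        groups = []
        for o in others:
            vals = np.array([dc[n][o] for n in ids if o in dc.get(n, {})])
            if len(vals) < 2:
                table[col][o] = ""  # stratum too small
                continue
            table[col][o] = _median_iqr(vals)
            groups.append(vals)
        if len(groups) >= 2 and any(np.ptp(np.concatenate(groups)) > 0 for _ in [0]):
            try:
                pvals[col] = f"{stats.kruskal(*groups).pvalue:.3g}"
            except ValueError:  # all values identical
                pvals[col] = ""
        else:
            pvals[col] = ""
    out = pd.DataFrame(table).reindex([reference_observer] + others)
    out.loc[reference_observer] = "—"
    out.loc["P-value"] = pd.Series(pvals)
    out.index.name = "observer"
    return out


def dc_diameter_analysis(sr: StudyResult) -> dict[str, float]:
    """Correlation and regression of per-nodule median DC on true diameter (cm).

    Returns the Spearman coefficient with its p-value and the OLS slope and
    intercept of median DC on diameter.  Constant DC reports NaN correlation.
    """
    if len(sr.manifest) < 10:
        raise ValueError("need at least 10 nodules")
    d = sr.manifest.true_diameter_cm.to_numpy()
    dc = sr.manifest.median_dc.to_numpy()
    if np.ptp(dc) == 0:
        warnings.warn("constant median DC: correlation undefined", stacklevel=2)
        return {"spearman_rs": float("nan"), "p": float("nan"),
                "slope": 0.0, "intercept": float(dc[0])}
    rs, p = stats.spearmanr(d, dc)
    slope, intercept = np.polyfit(d, dc, 1)
    return {
        "spearman_rs": float(rs),
        "p": float(p),
        "slope": float(slope),
        "intercept": float(intercept),
    }


GROUPINGS = ("feature_class", "image_type", "wavelet_subband", "log_sigma", "nodule_type")


def _grouped_occc(sr: StudyResult, grouping: str) -> dict[str, np.ndarray]:
    st = sr.stability
    if grouping == "feature_class":
        keys = FEATURE_CLASSES
        col = "feature_class"
    elif grouping == "image_type":
        keys = sorted(st.image_type.unique())
        col = "image_type"
    elif grouping == "wavelet_subband":
        keys = [b for b in st.wavelet_subband.dropna().unique()]
        col = "wavelet_subband"
    elif grouping == "log_sigma":
        keys = sorted(st.log_sigma_mm.dropna().unique())
        col = "log_sigma_mm"
    elif grouping == "nodule_type":
        return {
            t: sr.occc_by_type[t].dropna().to_numpy() for t in sr.occc_by_type.columns
        }
    else:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")
    return {
        str(k): st.loc[st[col] == k, "occc"].to_numpy()
        for k in keys
        if (st[col] == k).sum() > 0
    }


def subgroup_occc_comparison(sr: StudyResult, grouping: str) -> pd.DataFrame:
    """Median (IQR) OCCC per subgroup with omnibus and pairwise tests.

    Kruskal–Wallis across groups, then pairwise rank-sum (Mann–Whitney)
    tests with Bonferroni adjustment.  For ``nodule_type`` the OCCC is the
    per-type recomputation over that type's nodules.  Groups with fewer than
    2 features are dropped with a note.
    """
    groups = _grouped_occc(sr, grouping)
    dropped = [k for k, v in groups.items() if len(v) < 2]
    if dropped:
        warnings.warn(f"dropping subgroups with <2 features: {dropped}", stacklevel=2)
    groups = {k: v for k, v in groups.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 subgroups with >= 2 features")
    kw_p = float(stats.kruskal(*groups.values()).pvalue)
    rows = [
        {
            "grouping": grouping,
            "group": k,
            "n": len(v),
            "median_occc": float(np.median(v)),
            "iqr_occc": float(np.subtract(*np.percentile(v, [75, 25]))),
            "kruskal_wallis_p": kw_p,
            "comparison": "",
            "p_adjusted": float("nan"),
        }
        for k, v in groups.items()
    ]
    pairs = list(combinations(groups.keys(), 2))
    for a, b in pairs:
        p = float(stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue)
        rows.append(
            {
                "grouping": grouping,
                "group": "",
                "n": 0,
                "median_occc": float("nan"),
                "iqr_occc": float("nan"),
                "kruskal_wallis_p": kw_p,
                "comparison": f"{a} vs {b}",
                "p_adjusted": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def _persist(sr: StudyResult, out_path: Path) -> None:
    sr.manifest.to_csv(out_path / "study_nodules.csv", index=False)
    sr.features.to_csv(out_path / "features.csv")
    sr.occc_per_feature.rename_axis("feature").to_csv(out_path / "occc_per_feature.csv")
    stability_table(sr).to_csv(out_path / "stability_table.csv")
    dc_table(sr).to_csv(out_path / "dc_table.csv")
    tests = []
    for grouping in GROUPINGS:
        try:
            tests.append(subgroup_occc_comparison(sr, grouping))
        except ValueError:
            pass
    if tests:
        pd.concat(tests, ignore_index=True).to_csv(
            out_path / "subgroup_tests.csv", index=False
        )
    summary = {
        "n_nodules": int(len(sr.manifest)),
        "n_observers": len(sr.observer_ids),
        "master_seed": sr.design.master_seed,
        "n_features": int(sr.features.shape[1]),
        "n_excluded_nan_features": len(sr.excluded_features),
        "excluded_features": sr.excluded_features,
    }
    try:
        summary["dc_diameter"] = dc_diameter_analysis(sr)
    except ValueError:
        pass
    (out_path / "study_manifest.json").write_text(json.dumps(summary, indent=2))
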