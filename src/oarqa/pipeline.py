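"""End-to-end training, classification and the phantom experiment.

Training consumes a corpus of acceptable structure sets and produces one
:class:`~oarqa.core.OarModelBundle` per OAR type: sign-standardised feature
statistics, the Mahalanobis model, autoencoder weights, CCR bounds for the
pairs this OAR selects, and the connectedness threshold.  Classification
scores every contour of a structure set with the three single-contour
metrics, the CCR pair checks and the parts count, then (given thresholds)
combines the flags by logical OR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate, features, models, phantom, relational
from .core import Contour, OarModelBundle, StructureSet
from .features import CT_COLUMNS, FEATURE_NAMES, PC1_COLUMNS, PC2_COLUMNS
from .relational import BODY_LABEL

MODEL_TYPES = ("zscore", "md", "ae")

REPORT_COLUMNS = [
    "set_id", "oar_type", "zscore", "md", "ae", "parts",
    "ccr_flag", "conn_flag", "truth", "category", "severity", "detail",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the QA framework (defaults as described above)."""

    mad_k: float = 12.0
    ccr_percentile: float = 0.99
    ae_hidden: int = 18
    ae_l2: float = 0.005
    ae_max_epochs: int = 7000
    min_train_rows: int = 10
    parts_quantile: float = 0.9995
    seed: int = 0


def train_bundles(train_sets, ccr_pairs=phantom.DEFAULT_CCR_PAIRS,
                  config: TrainingConfig | None = None,
                  skip_small: bool = True) -> dict[str, OarModelBundle]:
    """Train all per-OAR models from a corpus of acceptable structure sets.

    OAR types with fewer than ``config.min_train_rows`` contours are
    skipped with a warning (or raise when ``skip_small`` is false) rather
    than silently underfit.  Contours from sets without a CT image are
    excluded from training (their CT features are undefined).
    """
    config = config or TrainingConfig()
    table = pd.concat([features.extract_features(s) for s in train_sets],
                      ignore_index=True)
    parts_counts: dict[str, list[int]] = {}
    for s in train_sets:
        for c in s:
            parts_counts.setdefault(c.oar_type, []).append(
                features.count_parts(c))
    pair_table = collect_pair_features(train_sets, ccr_pairs)

    bundles: dict[str, OarModelBundle] = {}
    seed_root = np.random.SeedSequence(config.seed)
    oar_types = sorted(table["oar_type"].unique())
    oar_seeds = dict(zip(oar_types,
                         seed_root.generate_state(len(oar_types)) % (2 ** 31)))
    for oar in oar_types:
        rows = table[table["oar_type"] == oar].copy()
        rows = rows.dropna(subset=list(CT_COLUMNS))
        if len(rows) < config.min_train_rows:
            msg = (f"{oar}: only {len(rows)} usable training contours "
                   f"(< {config.min_train_rows}); skipped")
            if not skip_small:
                raise ValueError(msg)
            warnings.warn(msg)
            continue
        bundles[oar] = _train_one(oar, rows, pair_table, parts_counts[oar],
                                  ccr_pairs, config, int(oar_seeds[oar]))
    return bundles


def _train_one(oar, rows, pair_table, counts, ccr_pairs, config, seed):
    rep1 = features.representative_eigenvector(rows[list(PC1_COLUMNS)].to_numpy())
    rep2 = features.representative_eigenvector(rows[list(PC2_COLUMNS)].to_numpy())
    oriented = orient_feature_table(rows, rep1, rep2)

    filtered, removed = models.mad_filter(oriented, list(FEATURE_NAMES),
                                          k=config.mad_k)
    stats = models.fit_feature_stats(filtered, list(FEATURE_NAMES))
    md = models.fit_md(filtered, list(FEATURE_NAMES))
    z = np.vstack([models.zscore_transform(x, stats)
                   for x in filtered[list(FEATURE_NAMES)].to_numpy()])
    ae = models.fit_autoencoder(z, hidden=config.ae_hidden, l2=config.ae_l2,
                                max_epochs=config.ae_max_epochs, seed=seed)

    bounds = []
    for sel, comp in ccr_pairs:
        if sel != oar:
            continue
        sub = pair_table[(pair_table["selected"] == sel)
                         & (pair_table["comparison"] == comp)]
        if len(sub) < 2:
            continue
        for feat in ("min_distance", "fractional_overlap"):
            bounds.append(relational.fit_ccr_bounds(
                sub[feat].to_numpy(), feat, selected_oar=sel,
                comparison_oar=comp, percentile=config.ccr_percentile))
    parts = relational.fit_parts_threshold(counts, oar_type=oar)

    return OarModelBundle(
        oar_type=oar, feature_names=list(FEATURE_NAMES),
        feature_mean=stats.mean, feature_std=stats.std,
        feature_median=stats.median, feature_mad=stats.mad,
        md_mean=md.mean, md_cov=md.cov, md_cov_inv=md.cov_inv,
        rep_pc1=rep1, rep_pc2=rep2,
        ae_weights={"w1": ae.w1, "b1": ae.b1, "w2": ae.w2, "b2": ae.b2},
        ccr_bounds=bounds, parts_threshold=parts.max_parts,
        parts_gamma=parts.gamma_params,
        n_train=len(filtered), n_removed_mad=len(removed),
    )


def orient_feature_table(rows: pd.DataFrame, rep1, rep2) -> pd.DataFrame:
    """Sign-standardise the PC vector columns against representatives."""
    out = rows.copy()
    for cols, rep in ((list(PC1_COLUMNS), rep1), (list(PC2_COLUMNS), rep2)):
        vecs = out[cols].to_numpy()
        flip = vecs @ np.asarray(rep) < 0
        vecs[flip] *= -1.0
        out[cols] = vecs
    return out


def collect_pair_features(sets, ccr_pairs) -> pd.DataFrame:
    """Pair features for every configured CCR pair present in each set."""
    rows = []
    for sset in sets:
        edt_cache: dict[str, np.ndarray] = {}
        for sel, comp in ccr_pairs:
            row = _pair_row(sset, sel, comp, edt_cache)
            if row is not None:
                rows.append(row)
    return pd.DataFrame(rows, columns=["set_id", "selected", "comparison",
                                       "min_distance", "fractional_overlap"])


def _get_contour(sset: StructureSet, name: str) -> Contour | None:
    if name == BODY_LABEL:
        return sset.body
    return sset.contours.get(name)


def _pair_row(sset, sel, comp, edt_cache):
    a = _get_contour(sset, sel)
    b = _get_contour(sset, comp)
    if a is None or b is None or a.is_empty or b.is_empty:
        return None
    overlap = features.fractional_overlap(a, b)
    if overlap > 0:
        dist = 0.0
    else:
        if comp not in edt_cache:
            edt_cache[comp] = features.distance_map(b)
        dist = features.min_surface_distance(a, b, edt_b=edt_cache[comp])
    return {"set_id": sset.set_id, "selected": sel, "comparison": comp,
            "min_distance": dist, "fractional_overlap": overlap}


def widen_bounds_to_acceptable(bundles: dict[str, OarModelBundle],
                               sets) -> int:
    """Widen CCR bounds so no acceptable pair in ``sets`` is flagged.

    Mirrors the manual step of setting percentile boundaries to minimise
    false positives on the validation set: any acceptable pair value
    outside its fitted interval extends that side of the interval.
    Returns the number of bounds adjusted.
    """
    pairs = sorted({(b.selected_oar, b.comparison_oar)
                    for bun in bundles.values() for b in bun.ccr_bounds})
    table = collect_pair_features(sets, pairs)
    adjusted = 0
    for bundle in bundles.values():
        for bound in bundle.ccr_bounds:
            sub = table[(table["selected"] == bound.selected_oar)
                        & (table["comparison"] == bound.comparison_oar)]
            if not len(sub):
                continue
            values = sub[bound.feature].to_numpy()
            lo, hi = float(values.min()), float(values.max())
            changed = False
            if lo < bound.lower:
                bound.lower, changed = lo, True
            if hi > bound.upper:
                bound.upper, changed = hi, True
            adjusted += changed
    return adjusted


# ---------------------------------------------------------------------------
# scoring


def score_structure_set(sset: StructureSet, bundles: dict[str, OarModelBundle],
                        only_oar: str | None = None) -> pd.DataFrame:
    """Model output metrics and CCR/connectedness flags for one set.

    When ``only_oar`` is given, only that contour is scored and only CCR
    pairs involving it are evaluated (used to assess an injected-error
    variant against the set's remaining acceptable contours).  A flagged
    CCR pair flags *both* member contours.
    """
    targets = [only_oar] if only_oar else [o for o in sset.oar_types
                                           if o in bundles]
    ccr_flags = {o: False for o in targets}
    edt_cache: dict[str, np.ndarray] = {}
    flagged_pairs = []
    for oar, bundle in bundles.items():
        for bound in bundle.ccr_bounds:
            involved = [n for n in (bound.selected_oar, bound.comparison_oar)
                        if n in targets]
            if only_oar is not None and only_oar not in involved:
                continue
            row = _pair_row(sset, bound.selected_oar, bound.comparison_oar,
                            edt_cache)
            if row is None:
                continue
            if relational.ccr_classify(row[bound.feature], bound):
                flagged_pairs.append((bound.selected_oar, bound.comparison_oar,
                                      bound.feature, row[bound.feature]))
                for name in involved:
                    ccr_flags[name] = True

    rows = []
    for oar in targets:
        contour = sset.contours.get(oar)
        bundle = bundles.get(oar)
        if contour is None or bundle is None:
            continue
        rows.append(_score_contour(contour, sset, bundle, ccr_flags[oar]))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df.attrs["flagged_pairs"] = flagged_pairs
    return df


def _score_contour(contour, sset, bundle, ccr_flag):
    feats = features._feature_row(contour, sset)
    x = np.array([feats[n] for n in FEATURE_NAMES], dtype=float)
    x = _orient_vector(x, bundle)
    stats = models.FeatureStats(names=bundle.feature_names,
                                mean=bundle.feature_mean,
                                std=bundle.feature_std,
                                median=bundle.feature_median,
                                mad=bundle.feature_mad)
    md = models.MdModel(mean=bundle.md_mean, cov=bundle.md_cov,
                        cov_inv=bundle.md_cov_inv)
    ae = models.AeModel(w1=bundle.ae_weights["w1"], b1=bundle.ae_weights["b1"],
                        w2=bundle.ae_weights["w2"], b2=bundle.ae_weights["b2"])
    parts = features.count_parts(contour)
    threshold = relational.PartsThreshold(oar_type=contour.oar_type,
                                          max_parts=bundle.parts_threshold)
    meta = contour.error_meta
    return {
        "set_id": contour.set_id or sset.set_id,
        "oar_type": contour.oar_type,
        "zscore": models.zscore_metric(x, stats),
        "md": models.md_metric(x, md),
        "ae": models.ae_metric(x, ae, stats),
        "parts": parts,
        "ccr_flag": bool(ccr_flag),
        "conn_flag": relational.connectedness_classify(parts, threshold),
        "truth": contour.truth_label or "",
        "category": meta.category if meta else "",
        "severity": meta.severity if meta else "",
        "detail": meta.detail if meta else "",
    }


def _orient_vector(x: np.ndarray, bundle: OarModelBundle) -> np.ndarray:
    names = list(FEATURE_NAMES)
    for cols, rep in ((PC1_COLUMNS, bundle.rep_pc1),
                      (PC2_COLUMNS, bundle.rep_pc2)):
        idx = [names.index(c) for c in cols]
        x[idx] = features.orient_eigenvector(x[idx], rep)
    return x


def apply_thresholds(report: pd.DataFrame, thresholds: dict[str, float],
                     model: str) -> pd.DataFrame:
    """Add single/combined flags for one model type to a score report."""
    out = report.copy()
    out["single_flag"] = out[model].to_numpy() > thresholds[model]
    out["combined_flag"] = evaluate.combine_flags(
        out["single_flag"], out["ccr_flag"], out["conn_flag"])
    return out


# ---------------------------------------------------------------------------
# the phantom experiment


@dataclass
class ExperimentResult:
    """Scores, tuned thresholds and summary metrics of a phantom study."""

    val_report: pd.DataFrame
    test_report: pd.DataFrame
    thresholds_alone: dict[str, float]
    thresholds_combined: dict[str, float]
    metrics: dict = field(default_factory=dict)
    bundles: dict = field(default_factory=dict)


def build_eval_report(sets, bundles, n_errors, seed,
                      config: phantom.PhantomConfig) -> pd.DataFrame:
    """Score all acceptable contours plus ``n_errors`` injected variants.

    Errors follow the clinical category/severity mix; each erroneous
    contour is evaluated inside its own structure set so CCR comparisons
    run against the set's remaining acceptable contours.
    """
    rng = np.random.default_rng(seed)
    parts = [score_structure_set(s, bundles) for s in sets]
    plan = phantom.plan_error_mix(n_errors, rng)
    eligible = [o for o in config.oar_names() if o in bundles]
    for i, (category, severity) in enumerate(plan):
        sset = sets[i % len(sets)]
        for attempt in range(10):
            oar = eligible[rng.integers(len(eligible))]
            params = {}
            if (category == "position" and severity == "major"
                    and rng.random() < 0.2):
                other = eligible[rng.integers(len(eligible))]
                if other != oar:
                    params = {"mode": "swap", "swap_with": sset[other]}
            spec = phantom.ErrorSpec(category=category, severity=severity,
                                     seed=int(rng.integers(2 ** 31)),
                                     params=params)
            try:
                bad = phantom.inject_error(sset[oar], sset.image, spec)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(f"could not inject {category} error")
        variant = sset.with_replaced(bad)
        parts.append(score_structure_set(variant, bundles, only_oar=oar))
    return pd.concat(parts, ignore_index=True)


def run_phantom_experiment(n_sets: int = 100, seed: int = 0,
                           n_val_errors: int = 100, n_test_errors: int = 30,
                           config: phantom.PhantomConfig | None = None,
                           training: TrainingConfig | None = None,
                           ) -> ExperimentResult:
    """Full study: generate, split 80/10/10, train, tune, evaluate.

    Thresholds are tuned on the validation report only; the test report is
    scored with the validation thresholds.
    """
    config = config or phantom.PhantomConfig()
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2 ** 31)
    training = training or TrainingConfig(seed=int(seeds[0]))
    sets = phantom.generate_corpus(config, n_sets, int(seeds[1]))
    n_train = int(round(0.8 * n_sets))
    n_val = int(round(0.1 * n_sets))
    train_sets = sets[:n_train]
    val_sets = sets[n_train:n_train + n_val]
    test_sets = sets[n_train + n_val:]

    bundles = train_bundles(train_sets, phantom.DEFAULT_CCR_PAIRS, training)
    widen_bounds_to_acceptable(bundles, val_sets)
    val = build_eval_report(val_sets, bundles, n_val_errors, int(seeds[2]),
                            config)
    test = build_eval_report(test_sets, bundles, n_test_errors, int(seeds[3]),
                             config)

    truth_val = val["truth"].to_numpy()
    fixed_val = evaluate.combine_flags(val["ccr_flag"], val["conn_flag"], False)
    thresholds_alone, thresholds_combined = {}, {}
    for m in MODEL_TYPES:
        thresholds_alone[m], _ = evaluate.tune_threshold(val[m], truth_val)
        thresholds_combined[m], _ = evaluate.tune_threshold(
            val[m], truth_val, fixed_flags=fixed_val)

    metrics = {}
    for split_name, rep in (("val", val), ("test", test)):
        truth = rep["truth"].to_numpy()
        fixed = evaluate.combine_flags(rep["ccr_flag"], rep["conn_flag"], False)
        split = {
            "ccr": evaluate.confusion_metrics(rep["ccr_flag"], truth),
            "connectedness": evaluate.confusion_metrics(rep["conn_flag"], truth),
        }
        for m in MODEL_TYPES:
            scores = rep[m].to_numpy()
            split[m] = evaluate.confusion_metrics(
                scores > thresholds_alone[m], truth)
            split[f"{m}_combined"] = evaluate.confusion_metrics(
                evaluate.combine_flags(scores > thresholds_combined[m],
                                       fixed, False), truth)
            split[f"{m}_auc"] = evaluate.roc_auc(scores, truth)
        metrics[split_name] = split
    return ExperimentResult(val_report=val, test_report=test,
                            thresholds_alone=thresholds_alone,
                            thresholds_combined=thresholds_combined,
                            metrics=metrics, bundles=bundles)


def report_to_csv(report: pd.DataFrame, path) -> None:
    """Write a score report with stable formatting (byte-reproducible)."""
    report.to_csv(path, index=False, float_format="%.10g")
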