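"""Evaluation engine: parent-coverage frameworks, sampling scenarios,
precision metrics, marker-panel selection, and a prediction-augmented
association scan.

Predictive frameworks partition F1 hybrids by how the training set covers
the parents of the test set:

* ``MP`` — both the mother and the father of every test F1 also parent
  some training F1 (easiest generalisation);
* ``M``  — test mothers are covered but no test father parents any
  training F1;
* ``P``  — the symmetric case (fathers covered, mothers unseen);
* ``neither`` — test F1s share no parent with any training F1 (hardest).

Every plan is machine-checked against its scheme's coverage predicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import baseline, gbdt
from .geno import EncodedMatrix
from .metrics import binary_auc, multiclass_ovr_auc, pearson_r
from .pedigree import Pedigree
from .pheno import PhenotypeTable, label_quantiles

logger = logging.getLogger(__name__)

#: Training:testing ratio grid used by the sampling scenarios.
RATIO_GRID = (9.0, 7.0, 5.0, 3.0, 1.0, 1 / 3, 1 / 5, 1 / 7, 1 / 9)


@dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    scheme: str
    seed: int
    ratio: float  # test fraction targeted
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class EvalReport:
    metric: str
    per_repeat: list[float]
    seeds: list[int]
    splits: list[dict]
    per_class: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        for v in self.per_repeat:
            if self.metric == "pearson_r" and not -1 <= v <= 1:
                raise ValueError("pearson r out of [-1, 1]")
            if self.metric in ("auc", "multiclass_auc") and not 0 <= v <= 1:
                raise ValueError("AUC out of [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_repeat))


@dataclass
class ScanResult:
    marker_ids: list[str]
    beta: np.ndarray
    p_value: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        if ((self.p_value <= 0) | (self.p_value > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Parent-coverage splits


def check_split(plan: SplitPlan, pedigree: Pedigree) -> bool:
    """Does the plan satisfy its scheme's parent-coverage predicate?"""
    parents = dict(zip(pedigree.f1_ids, zip(pedigree.mother, pedigree.father)))
    train_mothers = {parents[s][0] for s in plan.train_ids}
    train_fathers = {parents[s][1] for s in plan.train_ids}
    test_mothers = {parents[s][0] for s in plan.test_ids}
    test_fathers = {parents[s][1] for s in plan.test_ids}
    if plan.scheme == "MP":
        return test_mothers <= train_mothers and test_fathers <= train_fathers
    if plan.scheme == "M":
        return test_mothers <= train_mothers and \
            not (test_fathers & train_fathers)
    if plan.scheme == "P":
        return test_fathers <= train_fathers and \
            not (test_mothers & train_mothers)
    if plan.scheme == "neither":
        return not (test_mothers & train_mothers) and \
            not (test_fathers & train_fathers)
    if plan.scheme == "random":
        return True
    raise ValueError(f"unknown scheme {plan.scheme!r}")


def split_by_parent_coverage(pedigree: Pedigree, scheme: str,
                             test_fraction: float = 1 / 6,
                             seed: int = 0) -> SplitPlan:
    """Draw a train/test split honouring a parent-coverage scheme.

    The default 5:1 training-to-testing ratio gives ``test_fraction=1/6``.
    Splits are built by sampling parent sets first (held-out fathers for
    "M", held-out mothers for "P", both for "neither") and then assigning
    F1s; for "MP" test F1s are drawn greedily so both their parents stay
    covered by the remaining training F1s.
    """
    if scheme not in ("MP", "M", "P", "neither", "random"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    mothers, fathers = pedigree.mothers, pedigree.fathers
    target_test = max(1, int(np.floor(test_fraction * n)))

    if scheme == "random":
        perm = rng.permutation(n)
        test = [pedigree.f1_ids[i] for i in perm[:target_test]]
        train = [pedigree.f1_ids[i] for i in perm[target_test:]]
        return SplitPlan(train, test, scheme, seed, test_fraction)

    if scheme == "MP":
        mcount: dict[str, int] = {}
        fcount: dict[str, int] = {}
        for mo, fa in zip(pedigree.mother, pedigree.father):
            mcount[mo] = mcount.get(mo, 0) + 1
            fcount[fa] = fcount.get(fa, 0) + 1
        in_train = dict.fromkeys(pedigree.f1_ids, True)
        test: list[str] = []
        order = rng.permutation(n)
        while len(test) < target_test:
            picked = None
            for i in order:
                sid = pedigree.f1_ids[i]
                if not in_train[sid]:
                    continue
                mo, fa = pedigree.mother[i], pedigree.father[i]
                if mcount[mo] >= 2 and fcount[fa] >= 2:
                    picked = (sid, mo, fa)
                    break
            if picked is None:
                raise ValueError(
                    "MP scheme unsatisfiable at this test size: every "
                    "remaining F1 is the sole offspring of one of its "
                    "parents")
            sid, mo, fa = picked
            in_train[sid] = False
            test.append(sid)
            mcount[mo] -= 1
            fcount[fa] -= 1
            order = rng.permutation(n)
        train = [s for s in pedigree.f1_ids if in_train[s]]
        return SplitPlan(train, test, scheme, seed, test_fraction)

    if scheme in ("M", "P"):
        # hold out a parent set on the uncovered side
        held_side = fathers if scheme == "M" else mothers
        n_held = max(1, int(round(test_fraction * len(held_side))))
        if n_held >= len(held_side):
            raise ValueError(
                f"scheme {scheme}: cannot hold out all "
                f"{'fathers' if scheme == 'M' else 'mothers'}")
        held = set(rng.choice(held_side, size=n_held, replace=False).tolist())
        is_test_side = [
            (fa in held) if scheme == "M" else (mo in held)
            for mo, fa in zip(pedigree.mother, pedigree.father)]
        train = [s for s, t in zip(pedigree.f1_ids, is_test_side) if not t]
        pool = [s for s, t in zip(pedigree.f1_ids, is_test_side) if t]
        # covered side must actually be covered by the training F1s
        tr_cov = {dict(zip(pedigree.f1_ids, pedigree.mother))[s]
                  for s in train} if scheme == "M" else \
                 {dict(zip(pedigree.f1_ids, pedigree.father))[s]
                  for s in train}
        par_of = dict(zip(pedigree.f1_ids,
                          pedigree.mother if scheme == "M" else pedigree.father))
        pool = [s for s in pool if par_of[s] in tr_cov]
        if not pool:
            raise ValueError(
                f"scheme {scheme}: no test F1 has its covered parent "
                "among training parents")
        if len(pool) > target_test:
            pool = rng.choice(pool, size=target_test, replace=False).tolist()
        return SplitPlan(train, pool, scheme, seed, test_fraction)

    # neither: disjoint parent sets on both sides
    s = np.sqrt(test_fraction) / (np.sqrt(test_fraction)
                                  + np.sqrt(1 - test_fraction))
    n_mt = max(1, int(round(s * len(mothers))))
    n_ft = max(1, int(round(s * len(fathers))))
    if n_mt >= len(mothers) or n_ft >= len(fathers):
        raise ValueError("neither scheme: not enough parents to partition")
    mt = set(rng.choice(mothers, size=n_mt, replace=False).tolist())
    ft = set(rng.choice(fathers, size=n_ft, replace=False).tolist())
    test_pool, train_pool = [], []
    for sid, mo, fa in zip(pedigree.f1_ids, pedigree.mother, pedigree.father):
        if mo in mt and fa in ft:
            test_pool.append(sid)
        elif mo not in mt and fa not in ft:
            train_pool.append(sid)
    if not test_pool or not train_pool:
        raise ValueError("neither scheme: empty train or test pool")
    want_test = test_fraction / (1 - test_fraction) * len(train_pool)
    if len(test_pool) > want_test:
        k = max(1, int(round(want_test)))
        test_pool = rng.choice(test_pool, size=k, replace=False).tolist()
    else:
        k = int(round(len(test_pool) * (1 - test_fraction) / test_fraction))
        if len(train_pool) > k:
            train_pool = rng.choice(train_pool, size=k,
                                    replace=False).tolist()
    return SplitPlan(train_pool, test_pool, "neither", seed, test_fraction)


# ---------------------------------------------------------------------------
# Sampling-rate scenarios


def sampling_scenarios(ids, scenario: int, seed: int = 0, repeats: int = 30,
                       fixed_size: int | None = None) -> list[SplitPlan]:
    """Build the four sampling-rate benchmark designs.

    1 — fixed test size, train size swept over the 9 training:testing
    ratios (9:1 ... 1:9); 2 — fixed train size, test swept; 3 — fixed 9:1
    ratio, population size swept over 9 sizes from n down to n/9; 4 — same
    with the 1:9 ratio. Each grid point yields ``repeats`` random plans.
    Infeasible grid points are skipped with a warning.
    """
    if isinstance(ids, Pedigree):
        ids = list(ids.f1_ids)
    ids = list(ids)
    n = len(ids)
    if scenario not in (1, 2, 3, 4):
        raise ValueError("scenario must be 1..4")
    rng = np.random.default_rng(seed)
    plans: list[SplitPlan] = []

    def draw(pop, n_train, n_test, meta, r):
        for rep in range(repeats):
            sub_seed = int(rng.integers(2**31))
            sub_rng = np.random.default_rng(sub_seed)
            perm = sub_rng.permutation(len(pop))
            chosen = [pop[i] for i in perm[: n_train + n_test]]
            plans.append(SplitPlan(
                chosen[:n_train], chosen[n_train:], "random", sub_seed,
                n_test / (n_train + n_test),
                meta | {"repeat": rep, "ratio": r}))

    if scenario in (1, 2):
        fixed = fixed_size if fixed_size is not None else n // 10
        for r in RATIO_GRID:
            if scenario == 1:
                n_test = fixed
                n_train = int(np.floor(fixed * r))
            else:
                n_train = fixed
                n_test = int(np.floor(fixed / r))
            if n_train < 2 or n_test < 1 or n_train + n_test > n:
                warnings.warn(f"ratio {r}: infeasible grid point skipped",
                              stacklevel=2)
                continue
            draw(ids, n_train, n_test,
                 {"scenario": scenario, "n_train": n_train, "n_test": n_test},
                 r)
    else:
        lo = n / 9
        sizes = [int(round(n - t * (n - lo) / 8)) for t in range(9)]
        train_frac = 0.9 if scenario == 3 else 0.1
        for size in sizes:
            n_train = int(np.floor(size * train_frac))
            n_test = size - n_train
            if n_train < 2 or n_test < 1:
                warnings.warn(f"size {size}: infeasible grid point skipped",
                              stacklevel=2)
                continue
            draw(ids, n_train, n_test,
                 {"scenario": scenario, "size": size}, train_frac)
    return plans


# ---------------------------------------------------------------------------
# Model dispatch


def _resolve_xy(X):
    """(ids, float array) from EncodedMatrix or (ids, array) tuple."""
    if isinstance(X, EncodedMatrix):
        return list(X.sample_ids), X.to_array()
    ids, arr = X
    return list(ids), np.asarray(arr, dtype=float)


def fit_predict(model_spec, X_train, y_train, X_test) -> np.ndarray:
    """Fit a model spec and return test predictions (regression scale).

    ``model_spec`` is ``("gbdt", params)``, ``("ridge", {"lam": ...})`` or a
    callable ``f(X_train, y_train, X_test) -> predictions``.
    """
    if callable(model_spec):
        return np.asarray(model_spec(X_train, y_train, X_test), dtype=float)
    name, params = model_spec
    if name == "gbdt":
        model = gbdt.fit(X_train, y_train, **params)
        return gbdt.predict(model, X_test)
    if name == "ridge":
        model = baseline.fit_ridge(X_train, y_train, **params)
        return baseline.predict_ridge(model, X_test)
    raise ValueError(f"unknown model {name!r}")


def evaluate_regression(model_spec, X, y, plans: list[SplitPlan],
                        pedigree: Pedigree | None = None) -> EvalReport:
    """Fit on each plan's training F1s, record Pearson r on its test F1s."""
    ids, Xa = _resolve_xy(X)
    idx = {s: i for i, s in enumerate(ids)}
    y = np.asarray(y, dtype=float)
    per, seeds, meta = [], [], []
    for plan in plans:
        if pedigree is not None and not check_split(plan, pedigree):
            raise ValueError(f"plan violates scheme {plan.scheme!r}")
        tr = np.array([idx[s] for s in plan.train_ids])
        te = np.array([idx[s] for s in plan.test_ids])
        pred = fit_predict(model_spec, Xa[tr], y[tr], Xa[te])
        per.append(pearson_r(y[te], pred))
        seeds.append(plan.seed)
        meta.append({"scheme": plan.scheme, "n_train": len(tr),
                     "n_test": len(te), **plan.meta})
    return EvalReport("pearson_r", per, seeds, meta)


def _class_scores(model_spec, Xtr, ytr_codes, Xte, n_classes: int):
    """(n_test, K) class scores. Boosters score with class probabilities;
    scalar regressors (ridge) are relabelled by the training quantile cuts
    and contribute per-class indicator scores."""
    if not callable(model_spec) and model_spec[0] == "gbdt":
        params = model_spec[1]
        obj = "binary" if n_classes == 2 else f"multiclass:{n_classes}"
        model = gbdt.fit(Xtr, ytr_codes, objective=obj, **params)
        prob = gbdt.predict(model, Xte)
        if n_classes == 2:
            prob = np.column_stack([1 - prob, prob])
        return prob
    pred = fit_predict(model_spec, Xtr, ytr_codes.astype(float), Xte)
    # relabel predictions with cuts reproducing the training class sizes
    fr = np.bincount(ytr_codes, minlength=n_classes) / len(ytr_codes)
    if n_classes == 2:
        cut = np.quantile(pred, fr[0])
        lab = (pred > cut).astype(int)
    else:
        c1, c2 = np.quantile(pred, [fr[0], fr[0] + fr[1]])
        lab = np.where(pred <= c1, 0, np.where(pred <= c2, 1, 2))
    return np.eye(n_classes)[lab]


def evaluate_classification(model_spec, X, labels, plans: list[SplitPlan],
                            n_classes: int = 2) -> EvalReport:
    """Per-plan AUC: binary ROC AUC, or one-vs-rest AUC per class.

    ``labels`` may be integers 0..K-1 or the strings produced by
    ``pheno.label_quantiles`` ("low" < "mid" < "high"). Plans whose test
    fold misses a class entirely are skipped with a warning.
    """
    ids, Xa = _resolve_xy(X)
    idx = {s: i for i, s in enumerate(ids)}
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        order = ["low", "high"] if n_classes == 2 else ["low", "mid", "high"]
        codes = np.array([order.index(v) for v in labels.tolist()])
    else:
        codes = labels.astype(int)
    per, seeds, meta, per_class = [], [], [], []
    for plan in plans:
        tr = np.array([idx[s] for s in plan.train_ids])
        te = np.array([idx[s] for s in plan.test_ids])
        if len(set(codes[te].tolist())) < n_classes:
            warnings.warn("class absent from test fold; fold skipped",
                          stacklevel=2)
            continue
        scores = _class_scores(model_spec, Xa[tr], codes[tr], Xa[te],
                               n_classes)
        if n_classes == 2:
            per.append(binary_auc(codes[te], scores[:, 1]))
            per_class.append(None)
        else:
            aucs = multiclass_ovr_auc(codes[te], scores)
            per.append(float(np.nanmean(aucs)))
            per_class.append(aucs)
        seeds.append(plan.seed)
        meta.append({"scheme": plan.scheme, "n_train": len(tr),
                     "n_test": len(te), **plan.meta})
    metric = "auc" if n_classes == 2 else "multiclass_auc"
    return EvalReport(metric, per, seeds, meta, per_class)


# ---------------------------------------------------------------------------
# Marker-panel selection


@dataclass
class PanelResult:
    panel_sizes: list[int]
    ig_r: dict[int, list[float]]       # per-size precision, IG panels
    random_r: dict[int, list[float]]   # matched random-panel controls
    full_r: list[float]                # all markers, same splits
    ranked_markers: list[str]          # by summed IG over repeats

    def mean_ig(self, k: int) -> float:
        return float(np.mean(self.ig_r[k]))

    def mean_random(self, k: int) -> float:
        return float(np.mean(self.random_r[k]))


def select_marker_panel(X, y, panel_sizes, repeats: int = 30,
                        subsample: float = 0.8, seed: int = 0,
                        params: dict | None = None) -> PanelResult:
    """Information-gain marker-panel design with random-panel controls.

    Per repeat: fit a booster on a random ``subsample`` of the samples,
    rank markers by summed IG, retrain on each top-k panel and score the
    held-out samples; a size-matched random panel is scored on the same
    split as the control. Panel sizes above the marker count are skipped.
    """
    ids, Xa = _resolve_xy(X)
    y = np.asarray(y, dtype=float)
    n, m = Xa.shape
    params = params or {}
    sizes = [k for k in panel_sizes if k <= m]
    skipped = [k for k in panel_sizes if k > m]
    if skipped:
        warnings.warn(f"panel sizes {skipped} exceed marker count; skipped",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    ig_r = {k: [] for k in sizes}
    random_r = {k: [] for k in sizes}
    full_r = []
    total_gain = np.zeros(m)
    n_train = int(round(subsample * n))
    for rep in range(repeats):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = gbdt.fit(Xa[tr], y[tr], **params)
        full_r.append(pearson_r(y[te], gbdt.predict(model, Xa[te])))
        imp = gbdt.feature_importance(model)
        total_gain += imp.total_gain
        for k in sizes:
            # keep genome order within the panel so feature-index
            # tie-breaking matches a plain fit on the same markers
            top = sorted(imp.top(k))
            mk = gbdt.fit(Xa[tr][:, top], y[tr], **params)
            ig_r[k].append(
                pearson_r(y[te], gbdt.predict(mk, Xa[te][:, top])))
            rand = rng.choice(m, size=k, replace=False)
            mr = gbdt.fit(Xa[tr][:, rand], y[tr], **params)
            random_r[k].append(
                pearson_r(y[te], gbdt.predict(mr, Xa[te][:, rand])))
    order = np.lexsort((np.arange(m), -total_gain))
    marker_ids = X.marker_ids if isinstance(X, EncodedMatrix) \
        else [f"f{j}" for j in range(m)]
    return PanelResult(sizes, ig_r, random_r, full_r,
                       [marker_ids[j] for j in order])


# ---------------------------------------------------------------------------
# Association scan and augmentation


def association_scan(X, y) -> ScanResult:
    """Single-marker linear regression of y on the additive code.

    Per marker: slope and two-sided t-test p-value; missing calls are
    dropped pairwise; monomorphic markers get beta 0 and p = 1.
    """
    if isinstance(X, EncodedMatrix):
        if X.scheme != "additive012":
            raise ValueError("association_scan requires additive012 coding")
        marker_ids = list(X.marker_ids)
        Xa = X.to_array()
    else:
        Xa = np.asarray(X, dtype=float)
        marker_ids = [f"f{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n_all = Xa.shape[0]
    if n_all <= 2:
        raise ValueError("need more than 2 samples")

    valid = ~np.isnan(Xa)
    X0 = np.nan_to_num(Xa)
    nj = valid.sum(axis=0).astype(float)
    Sx = X0.sum(axis=0)
    Sxx = (X0 * X0).sum(axis=0)
    Sy = valid.T @ y
    Syy = valid.T @ (y * y)
    Sxy = X0.T @ y

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = nj * Sxy - Sx * Sy
        varx = nj * Sxx - Sx * Sx
        vary = nj * Syy - Sy * Sy
        beta = cov / varx
        r2 = cov * cov / (varx * vary)
        r2 = np.clip(r2, 0.0, 1.0)
        t2 = r2 * (nj - 2) / (1 - r2)
        p = 2 * stats.t.sf(np.sqrt(t2), nj - 2)
    mono = (varx <= 1e-12) | (nj < 3) | (vary <= 1e-12)
    beta = np.where(mono, 0.0, beta)
    p = np.where(mono, 1.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    return ScanResult(marker_ids, beta, p)


def augment_with_predictions(model, X_unphenotyped, P_observed: PhenotypeTable,
                             trait: str | None = None) -> PhenotypeTable:
    """Append model-predicted phenotypes for unphenotyped samples.

    Rows are flagged via ``observed``; an overlap between observed and
    unphenotyped samples is an error. ``model`` is a fitted BoostedModel
    or RidgeModel.
    """
    if trait is None:
        trait = P_observed.trait_names[0]
    ids_new, _ = _resolve_xy(X_unphenotyped)
    overlap = set(ids_new) & set(P_observed.sample_ids)
    if overlap:
        raise ValueError(
            f"{len(overlap)} samples appear in both observed and "
            "unphenotyped sets")
    if not ids_new:
        return P_observed
    if isinstance(model, baseline.RidgeModel):
        preds = baseline.predict_ridge(model, X_unphenotyped)
    else:
        preds = gbdt.predict(model, X_unphenotyped)
    t = P_observed.trait_names.index(trait)
    new_vals = np.full((len(ids_new), len(P_observed.trait_names)), np.nan)
    new_vals[:, t] = preds
    observed = np.concatenate([
        np.ones(P_observed.n_samples, dtype=bool)
        if P_observed.observed is None else P_observed.observed,
        np.zeros(len(ids_new), dtype=bool)])
    group = None
    if P_observed.group is not None:
        group = list(P_observed.group) + ["predicted"] * len(ids_new)
    return PhenotypeTable(
        list(P_observed.sample_ids) + ids_new,
        list(P_observed.trait_names),
        np.vstack([P_observed.values, new_vals]),
        group, observed)


def append_parental_features(X, pedigree: Pedigree,
                             parent_pheno: PhenotypeTable,
                             traits: list[str] | None = None):
    """Append each F1's mother's and father's own trait values as features.

    Returns ``(ids, array, feature_names)`` with the genotype columns first.
    Which parental traits to append is a caller choice (default: all).
    """
    ids, Xa = _resolve_xy(X)
    if traits is None:
        traits = list(parent_pheno.trait_names)
    pidx = {s: i for i, s in enumerate(parent_pheno.sample_ids)}
    par = dict(zip(pedigree.f1_ids, zip(pedigree.mother, pedigree.father)))
    cols = []
    names = []
    for side in (0, 1):
        for tr in traits:
            t = parent_pheno.trait_names.index(tr)
            col = np.array([
                parent_pheno.values[pidx[par[s][side]], t]
                if par[s][side] in pidx else np.nan
                for s in ids])
            cols.append(col)
            names.append(f"{'mother' if side == 0 else 'father'}_{tr}")
    base_names = X.marker_ids if isinstance(X, EncodedMatrix) \
        else [f"f{j}" for j in range(Xa.shape[1])]
    out = np.column_stack([Xa] + cols)
    return ids, out, list(base_names) + names
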