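"""Dataset construction and evaluation protocol.

* negative-pair generation: all site pairs within a protein except those
  whose both sites belong to the positive-site set;
* sample- and protein-grouped 10-fold cross-validation (protein mode keeps
  every pair of a protein in one fold, so validation proteins are unseen);
* seven metrics (AUC, AUPR, MCC, F1, recall, precision, ACC) at a fixed
  decision threshold;
* resampling significance test: ten stratified 70% subsamples, AUC/AUPR per
  method, Anderson–Darling normality check, then paired t-test (both normal)
  or Wilcoxon rank-sum;
* distance-matched control sets (Set-random, Seq-control, Str-control) and
  the per-feature distance-dependency probe built on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import PairDataset, PTMPair, PTMSiteRecord

DEFAULT_THRESHOLD = 0.15


# ---------------------------------------------------------------------------
# negative generation

def generate_negative_pairs(sites, positives):
    """All unordered site pairs per protein, minus pairs whose *both* sites
    occur in the positive-site set; labelled negative.

    A pair with one positive-set site and one other site is kept: only
    double-membership removes a candidate.
    """
    by_protein: dict = {}
    for s in sites:
        by_protein.setdefault(s.protein_id, {})[s.position] = s
    positive_sites: dict = {}
    positive_keys = set()
    for p in positives:
        positive_sites.setdefault(p.protein_id, set()).update(p.positions)
        positive_keys.add(p.key())
    negatives = []
    for pid in sorted(by_protein):
        site_map = by_protein[pid]
        pos_set = positive_sites.get(pid, set())
        for a, b in combinations(sorted(site_map), 2):
            if a in pos_set and b in pos_set:
                continue
            negatives.append(PTMPair(site_map[a], site_map[b],
                                     label="negative"))
    return negatives


# ---------------------------------------------------------------------------
# folds

@dataclass
class FoldAssignment:
    mode: str                  # 'sample' | 'protein'
    folds: np.ndarray          # fold index 1..k per pair, aligned to dataset
    k: int
    seed: int

    def split(self, fold: int):
        """(train_indices, validation_indices) for one fold."""
        val = np.where(self.folds == fold)[0]
        train = np.where(self.folds != fold)[0]
        return train, val


def make_fold_assignment(dataset: PairDataset, mode: str, k: int = 10,
                         seed: int = 0) -> FoldAssignment:
    """Balanced fold assignment; protein mode never splits a protein."""
    rng = np.random.default_rng(seed)
    n = len(dataset.pairs)
    folds = np.zeros(n, dtype=int)
    if mode == "sample":
        order = rng.permutation(n)
        for rank, idx in enumerate(order):
            folds[idx] = rank % k + 1
    elif mode == "protein":
        proteins = dataset.protein_ids()
        if len(proteins) < k:
            raise ValueError(f"protein mode needs at least {k} proteins, "
                             f"got {len(proteins)}")
        order = rng.permutation(len(proteins))
        fold_of = {proteins[idx]: rank % k + 1
                   for rank, idx in enumerate(order)}
        for i, pair in enumerate(dataset.pairs):
            folds[i] = fold_of[pair.protein_id]
    else:
        raise ValueError(f"unknown CV mode {mode!r}")
    return FoldAssignment(mode=mode, folds=folds, k=k, seed=seed)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricReport:
    auc: float
    aupr: float
    mcc: float
    f1: float
    recall: float
    precision: float
    acc: float
    threshold: float

    def as_dict(self) -> dict:
        return {"AUC": self.auc, "AUPR": self.aupr, "MCC": self.mcc,
                "F1": self.f1, "recall": self.recall,
                "precision": self.precision, "ACC": self.acc,
                "threshold": self.threshold}


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Closed-form thresholded metrics from confusion counts."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    acc = (tp + tn) / (tp + fn + fp + tn)
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return {"MCC": mcc, "F1": f1, "recall": recall,
            "precision": precision, "ACC": acc}


def compute_metrics(scores, labels, threshold: float = DEFAULT_THRESHOLD
                    ) -> MetricReport:
    """Seven-metric report; rank metrics are NaN (with a warning) when only
    one class is present."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class labels: AUC/AUPR undefined")
        auc = aupr = float("nan")
    else:
        auc = float(roc_auc_score(labels, scores))
        aupr = float(average_precision_score(labels, scores))
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    tn = int(np.sum(~calls & (labels == 0)))
    m = metrics_from_confusion(tp, fn, fp, tn)
    return MetricReport(auc=auc, aupr=aupr, mcc=m["MCC"], f1=m["F1"],
                        recall=m["recall"], precision=m["precision"],
                        acc=m["ACC"], threshold=threshold)


# ---------------------------------------------------------------------------
# resampling significance test

def _is_normal(values: np.ndarray, level: float = 0.05) -> bool:
    values = np.asarray(values, dtype=float)
    if np.std(values) < 1e-12:
        return False
    res = stats.anderson(values, dist="norm")
    levels = list(res.significance_level)
    crit = res.critical_values[levels.index(level * 100)]
    return bool(res.statistic < crit)


def significance_test(scores_a, scores_b, labels, n_resamples: int = 10,
                      fraction: float = 0.7, seed: int = 0) -> dict:
    """Compare two score vectors by stratified resampling.

    Draws ``n_resamples`` stratified subsamples of ``fraction`` of each
    class, computes AUC and AUPR for both methods on each, checks both value
    vectors for normality (Anderson–Darling at 0.05) and applies a paired
    t-test if both pass, otherwise a Wilcoxon rank-sum test.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    pos = np.where(labels == 1)[0]
    neg = np.where(labels == 0)[0]
    values = {"AUC": ([], []), "AUPR": ([], [])}
    draws = 0
    while draws < n_resamples:
        take = np.concatenate([
            rng.choice(pos, size=max(1, round(fraction * len(pos))),
                       replace=False),
            rng.choice(neg, size=max(1, round(fraction * len(neg))),
                       replace=False)])
        sub_labels = labels[take]
        if len(np.unique(sub_labels)) < 2:        # defensive; stratified
            continue
        draws += 1
        for name, fn in (("AUC", roc_auc_score),
                         ("AUPR", average_precision_score)):
            values[name][0].append(float(fn(sub_labels, scores_a[take])))
            values[name][1].append(float(fn(sub_labels, scores_b[take])))
    report = {}
    for name, (va, vb) in values.items():
        va, vb = np.array(va), np.array(vb)
        if np.allclose(va, vb):
            report[name] = {"values_a": va, "values_b": vb,
                            "test": "identical", "p_value": 1.0,
                            "normal_a": False, "normal_b": False}
            continue
        na, nb = _is_normal(va), _is_normal(vb)
        if na and nb:
            stat = stats.ttest_rel(va, vb)
            test = "paired-t"
        else:
            stat = stats.ranksums(va, vb)
            test = "wilcoxon-rank-sum"
        report[name] = {"values_a": va, "values_b": vb, "test": test,
                        "p_value": float(stat.pvalue),
                        "normal_a": na, "normal_b": nb}
    return report


# ---------------------------------------------------------------------------
# distance-matched control sets

def sequence_distance(pair: PTMPair) -> float:
    return float(abs(pair.site_b.position - pair.site_a.position))


def structural_distance(pair: PTMPair, structure) -> float:
    ca = structure.ca_coords()
    ia = structure.index_of(pair.site_a.position)
    ib = structure.index_of(pair.site_b.position)
    return float(np.linalg.norm(ca[ia] - ca[ib]))


def build_control_sets(dataset: PairDataset, mode: str, seed: int = 0
                       ) -> PairDataset:
    """Keep all positives and draw an equal number of negatives.

    ``set_random``: uniform draw (native distance distribution).
    ``seq_control`` / ``str_control``: negatives matched to the positives'
    sequence-separation / Cα-distance distribution by decile bins, with
    nearest-bin fallback (warned) when a bin runs out of negatives.
    """
    rng = np.random.default_rng(seed)
    positives = [p for p in dataset.pairs if p.label == "positive"]
    negatives = [p for p in dataset.pairs if p.label == "negative"]
    if not positives:
        raise ValueError("no positive pairs in dataset")
    if len(negatives) < len(positives):
        raise ValueError("not enough negatives to match the positives")
    if mode == "set_random":
        chosen = list(rng.choice(len(negatives), size=len(positives),
                                 replace=False))
        picked = [negatives[i] for i in chosen]
    elif mode in ("seq_control", "str_control"):
        if mode == "seq_control":
            dist = sequence_distance
            pos_d = np.array([dist(p) for p in positives])
            neg_d = np.array([dist(p) for p in negatives])
        else:
            pos_d = np.array([structural_distance(
                p, dataset.proteins[p.protein_id]) for p in positives])
            neg_d = np.array([structural_distance(
                p, dataset.proteins[p.protein_id]) for p in negatives])
        edges = np.quantile(pos_d, np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        pos_bins = np.digitize(pos_d, edges[1:-1])
        neg_bins = np.digitize(neg_d, edges[1:-1])
        available = {b: list(rng.permutation(np.where(neg_bins == b)[0]))
                     for b in range(10)}
        picked_idx = []
        for b in range(10):
            need = int(np.sum(pos_bins == b))
            pool = available[b]
            take, pool[:] = pool[:need], pool[need:]
            short = need - len(take)
            if short > 0:
                warnings.warn(f"bin {b}: only {len(take)} matched negatives; "
                              f"falling back to nearest bins for {short}")
                for offset in range(1, 10):
                    for nb in (b - offset, b + offset):
                        while short > 0 and 0 <= nb < 10 and available[nb]:
                            take.append(available[nb].pop(0))
                            short -= 1
            picked_idx.extend(take)
        picked = [negatives[int(i)] for i in picked_idx]
    else:
        raise ValueError(f"unknown control mode {mode!r}")
    return PairDataset(pairs=positives + picked, proteins=dataset.proteins)


# ---------------------------------------------------------------------------
# per-feature distance-dependency probe

def single_feature_probe(dataset: PairDataset, feature_extractor,
                         seed: int = 0, n_trees: int = 100,
                         cv_folds: int = 5) -> dict:
    """Random-forest cross-validated metrics of one pair feature on the
    three control sets; ``feature_extractor(control_dataset)`` must return
    an (n_pairs, d) matrix aligned to the control set's pairs."""
    from sklearn.model_selection import cross_val_predict

    reports = {}
    for mode in ("set_random", "seq_control", "str_control"):
        control = build_control_sets(dataset, mode, seed=seed)
        x = np.atleast_2d(np.asarray(feature_extractor(control), dtype=float))
        if x.shape[0] != len(control.pairs):
            x = x.T
        y = control.labels()
        forest = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=seed, n_jobs=1)
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=seed)
        scores = cross_val_predict(forest, x, y, cv=cv,
                                   method="predict_proba")[:, 1]
        reports[mode] = compute_metrics(scores, y)
    return reports


# ---------------------------------------------------------------------------
# full cross-validated pipeline evaluation

def run_cross_validation(dataset: PairDataset, provider, mode: str,
                         k: int = 10, seed: int = 0, threshold: float =
                         DEFAULT_THRESHOLD, **train_kwargs) -> dict:
    """Train and score the full three-classifier ensemble per fold.

    Returns per-fold and pooled MetricReports plus the pooled scores.
    """
    from .io import PairDataset as PD
    from .pipeline import predict_dataset, train_all

    assignment = make_fold_assignment(dataset, mode, k=k, seed=seed)
    pooled_scores = np.zeros(len(dataset.pairs))
    per_fold = []
    for fold in range(1, k + 1):
        train_idx, val_idx = assignment.split(fold)
        train_ds = PD(pairs=[dataset.pairs[i] for i in train_idx],
                      proteins=dataset.proteins)
        val_ds = PD(pairs=[dataset.pairs[i] for i in val_idx],
                    proteins=dataset.proteins)
        bundle = train_all(train_ds, provider, **train_kwargs)
        results = predict_dataset(bundle, val_ds)
        scores = np.array([r.p_final for r in results])
        pooled_scores[val_idx] = scores
        per_fold.append(compute_metrics(scores, val_ds.labels(), threshold))
    pooled = compute_metrics(pooled_scores, dataset.labels(), threshold)
    return {"per_fold": per_fold, "pooled": pooled,
            "scores": pooled_scores, "assignment": assignment}
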