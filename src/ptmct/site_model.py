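"""Descriptor-based crosstalk classifier.

For each residue descriptor the maximum, minimum and mean over the two PTM
sites are taken; the shortest path distance between the sites in the
Cα-contact network is the single pair-level descriptor. With the ten
residue descriptors this gives a 31-long feature vector, classified by a
500-tree random forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .descriptors import (RESIDUE_FEATURES, ResidueDescriptorSet,
                          shortest_path_distance)

PAIR_FEATURE_NAMES = tuple(
    f"{name}_{stat}" for name in RESIDUE_FEATURES
    for stat in ("max", "min", "mean")
) + ("shortest_path_distance",)


@dataclass
class PairFeatureVector:
    values: np.ndarray
    manifest: tuple = PAIR_FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.manifest),):
            raise ValueError("feature vector does not match its manifest")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite pair features")


def aggregate_pair_features(desc: ResidueDescriptorSet, contact_graph,
                            pair) -> PairFeatureVector:
    """(max, min, mean) per residue descriptor over the two sites, plus the
    inter-site shortest path distance; symmetric in site order."""
    pa, pb = pair.positions
    for p in (pa, pb):
        if p not in desc:
            raise KeyError(f"no descriptors for position {p}")
    va, vb = desc.values[pa], desc.values[pb]
    out = []
    for name in RESIDUE_FEATURES:
        a, b = va[name], vb[name]
        out.extend([max(a, b), min(a, b), 0.5 * (a + b)])
    out.append(float(shortest_path_distance(contact_graph, pa, pb)))
    return PairFeatureVector(np.array(out))


@dataclass
class SiteModel:
    forest: RandomForestClassifier
    manifest: tuple
    seed: int

    @property
    def n_trees(self):
        return len(self.forest.estimators_)

    def feature_importances(self) -> dict:
        return dict(zip(self.manifest, self.forest.feature_importances_))


def train_site_rf(features: np.ndarray, labels, n_trees: int = 500,
                  seed: int = 0, manifest=PAIR_FEATURE_NAMES) -> SiteModel:
    """Fit the 500-tree random forest on pair feature vectors."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    if features.shape[1] != len(manifest):
        raise ValueError("feature matrix does not match the manifest")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(features, labels)
    return SiteModel(forest=forest, manifest=tuple(manifest), seed=seed)


def site_predict(model: SiteModel, features, manifest=None) -> np.ndarray:
    """Crosstalk probability for each feature row. If a manifest is given it
    must contain the same names as the training manifest; columns are
    remapped to the training order."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if manifest is not None:
        manifest = tuple(manifest)
        if sorted(manifest) != sorted(model.manifest):
            raise ValueError("feature manifest does not match the model")
        order = [manifest.index(name) for name in model.manifest]
        features = features[:, order]
    elif features.shape[1] != len(model.manifest):
        raise ValueError("feature matrix does not match the model manifest")
    return model.forest.predict_proba(features)[:, 1]


def write_feature_table(features: np.ndarray, pairs, path,
                        manifest=PAIR_FEATURE_NAMES) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(("protein_id", "pos_a", "pos_b") + tuple(manifest))
                 + "\n")
        for row, pair in zip(features, pairs):
            cells = [pair.protein_id, str(pair.site_a.position),
                     str(pair.site_b.position)]
            cells += [f"{v:.6g}" for v in row]
            fh.write("\t".join(cells) + "\n")
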