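"""Structure-graph crosstalk classifier.

Each PTM site brings its spatial microenvironment — the 10 residues nearest
in Cα distance. The two sites plus both microenvironments form a pair graph
whose edges are (1) site–site, (2) site–own microenvironment, and (3)
chemically interconnected residue pairs *within* one microenvironment
(minimum heavy-atom distance at or below a cutoff, default 5 Å). Node
features are row-normalised structural embeddings. A two-layer GIN with
elementwise max aggregation updates the nodes; a fixed 22-slot concatenation
readout (site i, site j, the two microenvironments by ascending distance;
absent slots zero, shared nodes duplicated) is projected and classified.
The training loss is flooded: |L − b| + b with flood level b = 0.017, so it
never falls below b.

The update ``h_v ← fΘ(h_v + max_u h_u)`` has no (1+ε) self-weighting and
uses max rather than sum aggregation — a deliberate variant of the
canonical GIN formulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import autodiff as ad
from .autodiff import Adam, Tensor, as_tensor, parameter

K_NEIGHBORS = 10
N_SLOTS = 2 + 2 * K_NEIGHBORS          # 22
DEFAULT_CHEM_CUTOFF = 5.0              # Å, minimum heavy-atom distance


@dataclass
class GraphTrainConfig:
    learning_rate: float = 5e-6
    flood_level: float = 0.017
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.flood_level < 0:
            raise ValueError("flood level must be non-negative")


@dataclass
class Microenvironment:
    """A site and its k nearest residues by Cα distance (site excluded),
    sorted by ascending distance with ties broken by lower position."""

    site: int
    neighbors: list                    # positions

    def __len__(self):
        return len(self.neighbors)


def extract_microenvironment(structure, position: int, k: int = K_NEIGHBORS
                             ) -> Microenvironment:
    if len(structure) < 2:
        raise ValueError("structure needs at least 2 residues")
    idx = structure.index_of(position)      # raises for invalid positions
    ca = structure.ca_coords()
    d = np.linalg.norm(ca - ca[idx], axis=1)
    positions = np.asarray(structure.positions)
    order = np.lexsort((positions, d))
    neighbors = [int(positions[i]) for i in order if i != idx][:k]
    return Microenvironment(site=position, neighbors=neighbors)


@dataclass
class PairGraph:
    """Fixed-layout graph of two PTM sites and their microenvironments."""

    site_i: int
    site_j: int
    nodes: list                        # unique positions
    edges: set                         # frozenset pairs of positions
    node_features: np.ndarray          # (n_nodes, D_s), layer-normalised
    slots: list                        # 22 entries: position or None

    @property
    def n_nodes(self):
        return len(self.nodes)

    def node_index(self, position):
        return self.nodes.index(position)

    def adjacency(self) -> np.ndarray:
        n = self.n_nodes
        a = np.zeros((n, n), dtype=bool)
        for e in self.edges:
            u, v = tuple(e)
            iu, iv = self.node_index(u), self.node_index(v)
            a[iu, iv] = a[iv, iu] = True
        return a


def _row_normalise(x: np.ndarray) -> np.ndarray:
    m = x.mean(axis=-1, keepdims=True)
    s = x.std(axis=-1, keepdims=True)
    return (x - m) / np.maximum(s, 1e-8)


def _min_heavy_atom_distance(res_a, res_b) -> float:
    pa = np.array(list(res_a.atoms.values()))
    pb = np.array(list(res_b.atoms.values()))
    return float(np.min(np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)))


def build_pair_graph(structure, site_i: int, site_j: int, struct_emb,
                     chem_cutoff: float = DEFAULT_CHEM_CUTOFF,
                     k: int = K_NEIGHBORS) -> PairGraph:
    """Assemble the pair graph for two sites (symmetric in site order)."""
    if site_i == site_j:
        raise ValueError("pair sites must differ")
    site_i, site_j = sorted((site_i, site_j))
    env_i = extract_microenvironment(structure, site_i, k=k)
    env_j = extract_microenvironment(structure, site_j, k=k)
    nodes = sorted({site_i, site_j} | set(env_i.neighbors)
                   | set(env_j.neighbors))
    edges = {frozenset((site_i, site_j))}
    for site, env in ((site_i, env_i), (site_j, env_j)):
        for u in env.neighbors:
            if u != site:
                edges.add(frozenset((site, u)))
        for a_idx in range(len(env.neighbors)):
            for b_idx in range(a_idx + 1, len(env.neighbors)):
                u, v = env.neighbors[a_idx], env.neighbors[b_idx]
                if _min_heavy_atom_distance(
                        structure.residue_at(u),
                        structure.residue_at(v)) <= chem_cutoff:
                    edges.add(frozenset((u, v)))
    values = struct_emb.values if hasattr(struct_emb, "values") \
        else np.asarray(struct_emb)
    rows = np.array([values[structure.index_of(p)] for p in nodes])
    slots = [site_i, site_j]
    slots += env_i.neighbors + [None] * (k - len(env_i.neighbors))
    slots += env_j.neighbors + [None] * (k - len(env_j.neighbors))
    return PairGraph(site_i=site_i, site_j=site_j, nodes=nodes, edges=edges,
                     node_features=_row_normalise(rows), slots=slots)


# ---------------------------------------------------------------------------
# functional pieces (used directly by the oracle tests)

def gin_layer(graph: PairGraph, features: np.ndarray, W: np.ndarray,
              b: np.ndarray) -> np.ndarray:
    """One GIN update: h_v ← (h_v + max_{u∈N(v)} h_u) W + b."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != W.shape[0]:
        raise ValueError("feature/weight dimension mismatch")
    adj = graph.adjacency()
    out = np.empty((graph.n_nodes, W.shape[1]))
    for v in range(graph.n_nodes):
        nbrs = np.where(adj[v])[0]
        agg = features[nbrs].max(axis=0) if len(nbrs) else \
            np.zeros(features.shape[1])
        out[v] = (features[v] + agg) @ W + b
    return out


def graph_readout(graph: PairGraph, features: np.ndarray,
                  W_proj: np.ndarray) -> np.ndarray:
    """Concatenate final node features in the fixed 22-slot layout and
    project: absent slots contribute zeros, shared nodes fill every slot
    they occupy."""
    features = np.asarray(features, dtype=float)
    h = features.shape[1]
    rows = []
    for slot in graph.slots:
        rows.append(np.zeros(h) if slot is None
                    else features[graph.node_index(slot)])
    return np.concatenate(rows) @ W_proj


def flooding_loss(loss, b: float):
    """|L − b| + b: gradient ascent below the flood level, descent above."""
    if isinstance(loss, Tensor):
        return (loss - b).abs() + b
    return abs(loss - b) + b


class GraphModel:
    """Two-layer GIN + slot readout classifier over pair graphs."""

    def __init__(self, D_s: int, hidden: int = 32, proj: int = 64,
                 seed: int = 0, layout_hash: str = ""):
        rng = np.random.default_rng(seed)

        def init(*shape):
            return parameter(rng.standard_normal(shape) / np.sqrt(shape[0]))
        self.D_s, self.hidden, self.proj = D_s, hidden, proj
        self.layout_hash = layout_hash
        self.W1, self.b1 = init(D_s, hidden), parameter(np.zeros(hidden))
        self.W2, self.b2 = init(hidden, hidden), parameter(np.zeros(hidden))
        self.W_proj = init(N_SLOTS * hidden, proj)
        self.W_out = init(proj, 2)
        self.b_out = parameter(np.zeros(2))

    def parameters(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W_proj,
                self.W_out, self.b_out]

    # -- batched forward over padded graph arrays ---------------------------
    @staticmethod
    def pack(graphs) -> dict:
        """Pad graphs to fixed arrays: features (B, 23, D) with a zero row
        at index 22, adjacency masks, and slot indices (22 -> zero row)."""
        B = len(graphs)
        D = graphs[0].node_features.shape[1]
        feat = np.zeros((B, N_SLOTS + 1, D))
        adj = np.zeros((B, N_SLOTS + 1, N_SLOTS + 1))
        slot_idx = np.full((B, N_SLOTS), N_SLOTS, dtype=int)
        for g_i, g in enumerate(graphs):
            n = g.n_nodes
            feat[g_i, :n] = g.node_features
            adj[g_i, :n, :n] = g.adjacency()
            for s_i, slot in enumerate(g.slots):
                if slot is not None:
                    slot_idx[g_i, s_i] = g.node_index(slot)
        return {"feat": feat, "adj": adj, "slot_idx": slot_idx}

    def _gin_step(self, h: Tensor, adj: np.ndarray, W, b) -> Tensor:
        # neighbour elementwise max with -inf masking; isolated/padding
        # rows are zeroed afterwards
        mask = adj[:, :, :, None]                       # (B, N, N, 1)
        has_nbr = (adj.sum(axis=-1, keepdims=True) > 0)  # (B, N, 1)
        expanded = h.reshape(h.shape[0], 1, h.shape[1], h.shape[2])
        masked = expanded * mask + (-1e9) * (1.0 - mask)
        agg = masked.max(axis=2) * has_nbr
        return (h + agg) @ W + b

    def forward(self, packed: dict) -> Tensor:
        feat, adj, slot_idx = (packed["feat"], packed["adj"],
                               packed["slot_idx"])
        B = feat.shape[0]
        h = as_tensor(feat)
        h = self._gin_step(h, adj, self.W1, self.b1)
        h = self._gin_step(h, adj, self.W2, self.b2)
        rows = np.arange(B)[:, None]
        gathered = h[rows, slot_idx]                   # (B, 22, hidden)
        hg = gathered.reshape(B, N_SLOTS * self.hidden) @ self.W_proj
        logits = (hg @ self.W_out + self.b_out).leaky_relu(0.01)
        return ad.softmax(logits, axis=-1)

    def predict_proba(self, graphs) -> np.ndarray:
        return self.forward(self.pack(graphs)).data[:, 1]

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        meta = dict(D_s=self.D_s, hidden=self.hidden, proj=self.proj,
                    layout_hash=self.layout_hash)
        arrays = {f"p{k}": p.data for k, p in enumerate(self.parameters())}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, expected_layout_hash: str | None = None):
        blob = np.load(path, allow_pickle=False)
        meta = json.loads(str(blob["__meta__"]))
        if (expected_layout_hash is not None
                and meta["layout_hash"] != expected_layout_hash):
            raise ValueError("model was trained against a different "
                             "embedding layout")
        model = cls(meta["D_s"], meta["hidden"], meta["proj"],
                    layout_hash=meta["layout_hash"])
        for k, p in enumerate(model.parameters()):
            p.data = blob[f"p{k}"]
        return model


def graph_forward(model: GraphModel, graph: PairGraph) -> np.ndarray:
    """Probability pair (P_neg, P_pos) for one pair graph."""
    return model.forward(model.pack([graph])).data[0]


def train_graph(graphs, labels, config: GraphTrainConfig | None = None,
                model: GraphModel | None = None):
    """Train the GIN classifier with Adam on the flooded cross-entropy.

    Same early-stopping protocol as the sequence model (held-out AUPR,
    patience). Returns ``(model, log)``; every logged training loss is at
    least the flood level by construction.
    """
    from sklearn.metrics import average_precision_score

    config = config or GraphTrainConfig()
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = GraphModel(D_s=graphs[0].node_features.shape[1],
                           seed=config.seed)
    packed_all = model.pack(graphs)

    n = len(labels)
    idx = np.arange(n)
    val_idx = []
    for cls in (0, 1):
        members = rng.permutation(idx[labels == cls])
        take = max(1, int(round(config.val_fraction * len(members))))
        val_idx.extend(members[:take])
    val_idx = np.array(sorted(val_idx))
    train_idx = np.setdiff1d(idx, val_idx)

    def subset(ix):
        return {k: v[ix] for k, v in packed_all.items()}

    opt = Adam(model.parameters(), lr=config.learning_rate)
    log = {"train_loss": [], "val_aupr": []}
    best = (-np.inf, None)
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            probs = model.forward(subset(batch))
            picked = probs[np.arange(len(batch)), labels[batch]]
            ce = -(picked + 1e-12).log().mean()
            loss = flooding_loss(ce, config.flood_level)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        scores = model.forward(subset(val_idx)).data[:, 1]
        aupr = float(average_precision_score(labels[val_idx], scores))
        log["train_loss"].append(float(np.mean(losses)))
        log["val_aupr"].append(aupr)
        if aupr > best[0] + 1e-6:
            best = (aupr, [p.data.copy() for p in model.parameters()])
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    if best[1] is not None:
        for p, data in zip(model.parameters(), best[1]):
            p.data = data
    return model, log
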