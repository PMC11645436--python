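"""Residue embeddings, attention-map pair features and structural embeddings.

All embedding sources sit behind one provider contract so that the models
never know where their features come from. A protein language model supplies
per-residue embeddings (last hidden layer) and per-head L×L attention maps;
for a residue pair (i, j) the two scores A[i,j] and A[j,i] from every map are
concatenated into the pair feature — with the reference configuration of 33
layers × 20 heads that is 660 maps and a 1320-long vector. A structural
model supplies per-residue structural embeddings.

The :class:`SyntheticProvider` is a fully deterministic stand-in used for
testing and simulation: residue embeddings are seeded functions of
(position, residue identity), attention rows are seeded positive vectors
normalised to sum one (optionally biased towards spatially close residue
pairs to plant learnable signal), and structural embeddings are seeded
projections of soft distance histograms, hence exactly invariant under
rigid-body motion.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: reference protein-language-model geometry: 33 layers x 20 heads -> 660 maps
REFERENCE_N_LAYERS = 33
REFERENCE_N_HEADS = 20


def _stable_hash(text: str) -> int:
    return int.from_bytes(
        hashlib.blake2b(text.encode(), digest_size=8).digest(), "big")


@dataclass
class ResidueEmbeddingMatrix:
    values: np.ndarray          # (L, D_e)
    provider_id: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("residue embedding must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite residue embedding values")


@dataclass
class AttentionMapStack:
    maps: np.ndarray            # (n_layers, n_heads, L, L), row-stochastic

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("attention stack must be 4-D")
        rows = self.maps.sum(axis=-1)
        if np.any(self.maps < -1e-12) or np.any(np.abs(rows - 1.0) > 1e-5):
            raise ValueError("attention rows must be non-negative and sum to 1")

    @property
    def n_layers(self):
        return self.maps.shape[0]

    @property
    def n_heads(self):
        return self.maps.shape[1]

    @property
    def seq_len(self):
        return self.maps.shape[2]


@dataclass
class PairAttentionVector:
    """Attention scores (A[i,j], A[j,i]) from every map, layer-major."""

    values: np.ndarray
    layout: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("pair attention scores must lie in [0, 1]")


@dataclass
class StructuralEmbeddingMatrix:
    values: np.ndarray          # (L, D_s)
    provider_id: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or not np.all(np.isfinite(self.values)):
            raise ValueError("invalid structural embedding matrix")


class EmbeddingProvider:
    """Contract every embedding source implements.

    Attributes ``n_layers``, ``n_heads``, ``D_e``, ``D_s`` fix all output
    shapes together with the sequence length; ``deterministic`` providers
    return identical output for identical input.
    """

    provider_id = "abstract"
    deterministic = True
    has_structure = True

    n_layers: int
    n_heads: int
    D_e: int
    D_s: int

    def embed_residues(self, sequence: str) -> ResidueEmbeddingMatrix:
        raise NotImplementedError

    def attention_maps(self, sequence: str, structure=None) -> AttentionMapStack:
        raise NotImplementedError

    def embed_structure(self, structure) -> StructuralEmbeddingMatrix:
        raise NotImplementedError

    @property
    def layout(self) -> str:
        return (f"v1;layer-major;head;(Aij,Aji);n_layers={self.n_layers};"
                f"n_heads={self.n_heads};D_e={self.D_e};D_s={self.D_s}")

    def layout_hash(self) -> str:
        return hashlib.blake2b(self.layout.encode(), digest_size=8).hexdigest()


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")


@dataclass
class SyntheticProvider(EmbeddingProvider):
    """Deterministic seeded provider with optional planted signal.

    ``contact_bias > 0`` inflates attention scores A[i,j] for residue pairs
    whose Cα distance is below ``contact_threshold`` (requires passing the
    structure to :meth:`attention_maps`). ``register_signal`` shifts residue
    embeddings at chosen positions along a seeded direction, planting a
    sequence-level class signal.
    """

    seed: int = 0
    n_layers: int = REFERENCE_N_LAYERS
    n_heads: int = REFERENCE_N_HEADS
    D_e: int = 32
    D_s: int = 16
    contact_bias: float = 0.0
    contact_threshold: float = 12.0
    deterministic: bool = True
    has_structure: bool = True
    _signals: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for name in ("n_layers", "n_heads", "D_e", "D_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.provider_id = f"synthetic-{self.seed}"

    # -- planted class signal ----------------------------------------------
    def register_signal(self, sequence: str, positions, strength: float) -> None:
        """Shift the residue and structural embeddings of ``positions``
        (1-based) by ``strength`` along fixed seeded unit directions for
        this sequence."""
        self._signals[sequence] = (tuple(sorted(set(positions))), float(strength))

    def _signal_direction(self, dim: int, tag: int) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, tag]))
        v = rng.standard_normal(dim)
        return v / np.linalg.norm(v)

    # -- contract ----------------------------------------------------------
    def embed_residues(self, sequence: str) -> ResidueEmbeddingMatrix:
        _check_sequence(sequence)
        L = len(sequence)
        out = np.empty((L, self.D_e))
        for p, aa in enumerate(sequence, start=1):
            rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, p, ord(aa)]))
            out[p - 1] = rng.standard_normal(self.D_e)
        if sequence in self._signals:
            positions, strength = self._signals[sequence]
            direction = self._signal_direction(self.D_e, 917)
            for p in positions:
                out[p - 1] += strength * direction
        return ResidueEmbeddingMatrix(out, provider_id=self.provider_id)

    def attention_maps(self, sequence: str, structure=None) -> AttentionMapStack:
        _check_sequence(sequence)
        L = len(sequence)
        rng = np.random.default_rng(np.random.SeedSequence(
            [self.seed, 311, _stable_hash(sequence)]))
        maps = rng.random((self.n_layers, self.n_heads, L, L)) + 0.05
        if self.contact_bias > 0.0:
            if structure is None:
                raise ValueError(
                    "contact-biased attention needs the structure")
            ca = structure.ca_coords()
            if len(ca) != L:
                raise ValueError("structure length does not match sequence")
            d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
            close = (d < self.contact_threshold) & ~np.eye(L, dtype=bool)
            maps = maps + self.contact_bias * close[None, None, :, :]
        maps /= maps.sum(axis=-1, keepdims=True)
        return AttentionMapStack(maps)

    def embed_structure(self, structure) -> StructuralEmbeddingMatrix:
        """Rigid-motion-invariant node features: a soft histogram of the
        residue's Cα distance profile blended with a seeded encoding of the
        residue identity (structural encoders consume residue types too)."""
        ca = structure.ca_coords()
        L = len(ca)
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        centers = np.linspace(2.0, 32.0, 16)
        # soft distance histogram: smooth, hence exactly rigid-motion invariant
        kern = np.exp(-((d[:, :, None] - centers[None, None, :]) ** 2)
                      / (2 * 2.0 ** 2))
        idx = np.arange(L)
        kern[idx, idx, :] = 0.0  # drop self-distance term
        hist = kern.sum(axis=1) / max(L - 1, 1)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 577]))
        proj = rng.standard_normal((16, self.D_s)) / np.sqrt(16)
        out = hist @ proj
        seq = structure.sequence
        for aa in set(seq):
            aa_rng = np.random.default_rng(
                np.random.SeedSequence([self.seed, 733, ord(aa)]))
            code = aa_rng.standard_normal(self.D_s)
            out[[k for k, c in enumerate(seq) if c == aa]] += code
        if seq in self._signals:
            positions, strength = self._signals[seq]
            direction = self._signal_direction(self.D_s, 919)
            for p in positions:
                out[p - 1] += strength * direction
        return StructuralEmbeddingMatrix(out, provider_id=self.provider_id)


def make_synthetic_provider(seed: int = 0,
                            n_layers: int = REFERENCE_N_LAYERS,
                            n_heads: int = REFERENCE_N_HEADS,
                            D_e: int = 32, D_s: int = 16,
                            contact_bias: float = 0.0,
                            contact_threshold: float = 12.0) -> SyntheticProvider:
    """Build the deterministic synthetic embedding provider."""
    return SyntheticProvider(seed=seed, n_layers=n_layers, n_heads=n_heads,
                             D_e=D_e, D_s=D_s, contact_bias=contact_bias,
                             contact_threshold=contact_threshold)


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the provider contract)

def embed_residues(provider: EmbeddingProvider, sequence: str
                   ) -> ResidueEmbeddingMatrix:
    emb = provider.embed_residues(sequence)
    if emb.values.shape != (len(sequence), provider.D_e):
        raise ValueError("provider returned wrong embedding shape")
    return emb


def attention_maps(provider: EmbeddingProvider, sequence: str, structure=None
                   ) -> AttentionMapStack:
    stack = provider.attention_maps(sequence, structure=structure)
    expected = (provider.n_layers, provider.n_heads,
                len(sequence), len(sequence))
    if stack.maps.shape != expected:
        raise ValueError("provider returned wrong attention shape")
    return stack


def pair_attention_vector(stack: AttentionMapStack, i: int, j: int
                          ) -> PairAttentionVector:
    """Extract the pair feature for 1-based positions (i, j).

    Layout is layer-major, then head, then (A[i,j], A[j,i]) per map, giving
    a vector of length 2 × n_layers × n_heads.
    """
    L = stack.seq_len
    if i == j:
        raise ValueError("pair positions must differ")
    for p in (i, j):
        if not 1 <= p <= L:
            raise ValueError(f"position {p} outside [1, {L}]")
    a_ij = stack.maps[:, :, i - 1, j - 1]          # (n_layers, n_heads)
    a_ji = stack.maps[:, :, j - 1, i - 1]
    values = np.stack([a_ij, a_ji], axis=-1).reshape(-1)
    layout = (f"v1;layer-major;head;(Aij,Aji);n_layers={stack.n_layers};"
              f"n_heads={stack.n_heads}")
    return PairAttentionVector(values, layout)


def save_embedding(matrix, path) -> None:
    """Cache an embedding matrix to ``<path>.npy`` with a JSON sidecar
    (``<path>.json``) recording provider id and shape."""
    import json

    path = str(path)
    np.save(path + ".npy", matrix.values)
    sidecar = {"provider_id": getattr(matrix, "provider_id", "unknown"),
               "shape": list(matrix.values.shape),
               "kind": type(matrix).__name__}
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh)


def load_embedding(path, expected_provider_id: str | None = None):
    """Load a cached embedding matrix; refuses a provider-id mismatch."""
    import json

    path = str(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    if (expected_provider_id is not None
            and sidecar["provider_id"] != expected_provider_id):
        raise ValueError(
            f"cached embedding from provider {sidecar['provider_id']!r}, "
            f"expected {expected_provider_id!r}")
    values = np.load(path + ".npy")
    cls = {"ResidueEmbeddingMatrix": ResidueEmbeddingMatrix,
           "StructuralEmbeddingMatrix": StructuralEmbeddingMatrix}[
        sidecar["kind"]]
    return cls(values, provider_id=sidecar["provider_id"])


def embed_structure(provider: EmbeddingProvider, structure
                    ) -> StructuralEmbeddingMatrix:
    if not provider.has_structure:
        raise ValueError(
            f"provider {provider.provider_id} has no structural capability")
    emb = provider.embed_structure(structure)
    if emb.values.shape != (len(structure), provider.D_s):
        raise ValueError("provider returned wrong structural shape")
    return emb
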