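"""Weighted integration of the three classifiers.

    P_str   = α · P_graph + (1 − α) · P_site
    P_final = β · P_seq   + (1 − β) · P_str

with the optimal weights α = β = 0.65 and decision cutoff 0.15 (the cutoff
is small because negatives heavily outnumber positives). A pair is called
crosstalk when P_final ≥ cutoff; the boundary counts as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

ALPHA_DEFAULT = 0.65
BETA_DEFAULT = 0.65
CUTOFF_DEFAULT = 0.15


@dataclass
class EnsembleConfig:
    alpha: float = ALPHA_DEFAULT
    beta: float = BETA_DEFAULT
    cutoff: float = CUTOFF_DEFAULT

    def __post_init__(self):
        for name in ("alpha", "beta", "cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PredictionResult:
    protein_id: str
    pos_a: int
    pos_b: int
    p_seq: float
    p_graph: float
    p_site: float
    p_str: float
    p_final: float
    call: str


def integrate(p_seq: float, p_graph: float, p_site: float,
              config: EnsembleConfig | None = None):
    """Return (P_str, P_final) from the three classifier probabilities."""
    config = config or EnsembleConfig()
    for name, v in (("p_seq", p_seq), ("p_graph", p_graph),
                    ("p_site", p_site)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    p_str = config.alpha * p_graph + (1.0 - config.alpha) * p_site
    p_final = config.beta * p_seq + (1.0 - config.beta) * p_str
    return p_str, p_final


def classify(p_final: float, cutoff: float = CUTOFF_DEFAULT) -> str:
    """'crosstalk' iff P_final ≥ cutoff."""
    if not 0.0 <= p_final <= 1.0:
        raise ValueError("p_final must lie in [0, 1]")
    return "crosstalk" if p_final >= cutoff else "no-crosstalk"


def make_result(pair, p_seq: float, p_graph: float, p_site: float,
                config: EnsembleConfig | None = None) -> PredictionResult:
    config = config or EnsembleConfig()
    p_str, p_final = integrate(p_seq, p_graph, p_site, config)
    return PredictionResult(
        protein_id=pair.protein_id, pos_a=pair.site_a.position,
        pos_b=pair.site_b.position, p_seq=p_seq, p_graph=p_graph,
        p_site=p_site, p_str=p_str, p_final=p_final,
        call=classify(p_final, config.cutoff))
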