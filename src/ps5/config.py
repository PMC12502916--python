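"""Tunable parameters of the PS5 pipeline.

Analysis defaults follow the method's published recommendations: gamma = 2
(the power emphasis that trades off sparse vs dense signal detection),
R = 50 sample splits, B = 10 000 Monte-Carlo draws, MCP concavity a = 3,
10-fold cross-validation over a 100-value penalty ladder.  Simulation
studies use a lighter configuration (B = 1000, 5-fold CV, 50-value ladder)
reachable via :meth:`PS5Config.simulation`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["PS5Config"]


@dataclass(frozen=True)
class PS5Config:
    gamma: float = 2.0
    mc_draws: int = 10_000          # B
    mcp_a: float = 3.0
    selection_criterion: str = "ebic"   # "ebic" or "cv"
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    cd_tol: float = 1e-7
    cd_max_sweeps: int = 10_000
    fdr_q: float = 0.01             # BY threshold used in applications
    fwer_alpha: float = 0.05

    def replace(self, **kwargs) -> "PS5Config":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def simulation(cls, **kwargs) -> "PS5Config":
        """Reduced-cost configuration for replicated simulation studies."""
        base = dict(mc_draws=1000, cv_folds=5, n_lambda=50)
        base.update(kwargs)
        return cls(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
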