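"""Shared MCMC chain settings."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MCMCSettings"]


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length defaults: 13 000 iterations, 3 000 burn-in, thin 10,
    leaving exactly 1 000 retained draws."""

    n_iter: int = 13_000
    burn_in: int = 3_000
    thin: int = 10

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin
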