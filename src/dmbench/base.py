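"""Shared result container for the association methods."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AssocResult", "METHODS"]

METHODS = ("poisson", "negbin", "voom_lm", "zig")


@dataclass(frozen=True)
class AssocResult:
    """One OTU x method association test.

    ``stat`` is a Wald z (poisson), LRT chi-square (negbin) or moderated t
    (voom_lm, zig).  ``pvalue`` is set to 1 with ``converged=False`` when the
    fit is non-estimable, so result tables stay rectangular.
    """

    otu_id: str
    method: str
    coef: float
    se: float
    stat: float
    pvalue: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("pvalue must lie in [0, 1]")
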