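"""Tunable run parameters with the defaults used for integrated interactomes."""

from __future__ import annotations

from dataclasses import asdict, dataclass


@dataclass
class RunConfig:
    """All tunable parameters of a full analysis run.

    Defaults follow the integrated-network parameterization: search bound
    ``l_max = 5`` interactions, subpaths of length 3-4 examined, minimum
    centrality 3, 10,000 degree-preserving permutations, FDR threshold 0.25.
    For a PPI-only network ``l_max = 4`` with a 2-3 subpath window is the
    customary choice; both are one to two interactions below the search bound.
    """

    l_max: int = 5
    len_min: int = 3
    len_max: int = 4
    min_centrality: int = 3
    n_replicates: int = 10_000
    degree_preserving: bool = True
    fdr_threshold: float = 0.25
    seed: int = 0
    count_endpoints: bool = True  # endpoints count toward node centrality
    pseudocount: bool = False  # p = (r+1)/(N+1) instead of r/N
    pool_bh: bool = False  # adjust nodes and subpaths as one family

    def __post_init__(self) -> None:
        if self.l_max < 1:
            raise ValueError("l_max must be a positive integer")
        if not (1 <= self.len_min <= self.len_max):
            raise ValueError("require 1 <= len_min <= len_max")
        if self.len_max > self.l_max:
            raise ValueError("len_max must not exceed l_max")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.min_centrality < 0:
            raise ValueError("min_centrality must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
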