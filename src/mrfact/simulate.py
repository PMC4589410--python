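"""Synthetic populations of highly similar sequences, and desk-scale benchmarks.

The generator emulates the kind of data referential factorization is built
for: a population of genomes that are small mutations of a common ancestor.
One base sequence is drawn uniformly over {A,C,G,T}; every reference and
every to-be-factorized sequence is an independent mutant of that base (a
star phylogeny), with SNPs at rate ``p_snp`` (substitution to a different
uniform base) and indel events at rate ``p_indel`` with geometrically
distributed lengths.  Three presets mimic the similarity regimes of the
species the method targets -- human chromosomes (most similar), Arabidopsis
thaliana chromosomes, and yeast genomes (least similar).

The benchmark helpers reproduce the *shape* of the multi-reference effect
at desk scale: the mean RME count as a function of the number of references
decays and is well fitted by a power law ``a * n^b`` on a log-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .factorize import FactorizerConfig, factorize_optimal
from .model import ReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Similarity presets, ordered from most to least similar.  Rates are per
#: base: human-like ~1 variant site per kb (SNP-dominated), at-like ~5/kb,
#: yeast-like ~2% divergence.
PROFILES: dict[str, dict] = {
    "human-like": {"p_snp": 0.001, "p_indel": 0.0001, "indel_mean": 3.0},
    "at-like": {"p_snp": 0.005, "p_indel": 0.0005, "indel_mean": 3.0},
    "yeast-like": {"p_snp": 0.02, "p_indel": 0.002, "indel_mean": 3.0},
}


@dataclass
class SynthConfig:
    """Parameters of one synthetic population.

    All output is deterministic given ``seed``.
    """

    base_length: int = 20_000
    n_refs: int = 5
    n_seqs: int = 10
    p_snp: float = 0.001
    p_indel: float = 0.0001
    indel_mean: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_length < 1:
            raise ValueError("base_length must be >= 1")
        for name in ("p_snp", "p_indel"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.indel_mean < 1.0:
            raise ValueError("indel_mean must be >= 1")

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "SynthConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; "
                             f"choose from {sorted(PROFILES)}")
        kwargs = dict(PROFILES[profile])
        kwargs.update(overrides)
        return cls(**kwargs)


def _to_str(idx: np.ndarray) -> str:
    return _BASES[idx].tobytes().decode("ascii")


def _mutate(base: np.ndarray, rng: np.random.Generator,
            p_snp: float, p_indel: float, indel_mean: float) -> np.ndarray:
    arr = base.copy()
    n = len(arr)
    mask = rng.random(n) < p_snp
    k = int(mask.sum())
    if k:
        # shift by 1..3 mod 4: always a *different* base
        arr[mask] = (arr[mask] + rng.integers(1, 4, k, dtype=arr.dtype)) % 4
    n_events = int(rng.binomial(n, p_indel))
    if n_events:
        positions = np.sort(rng.integers(0, n, n_events))
        is_ins = rng.random(n_events) < 0.5
        lens = rng.geometric(1.0 / indel_mean, n_events)
        pieces = []
        prev = 0
        for pos, ins, ln in zip(positions.tolist(), is_ins.tolist(), lens.tolist()):
            if pos < prev:  # swallowed by a previous deletion
                continue
            pieces.append(arr[prev:pos])
            if ins:
                pieces.append(rng.integers(0, 4, ln, dtype=arr.dtype))
                prev = pos
            else:
                prev = min(n, pos + ln)
        pieces.append(arr[prev:])
        arr = np.concatenate(pieces) if pieces else arr[:0]
    if len(arr) == 0:
        arr = rng.integers(0, 4, 1, dtype=base.dtype)
    return arr


def simulate_population(cfg: SynthConfig) -> tuple[list[tuple[str, str]],
                                                   list[tuple[str, str]]]:
    """Generate ``(references, sequences)`` as ``(name, seq)`` pair lists."""
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, 4, cfg.base_length, dtype=np.uint8)
    refs = [(f"ref{i + 1}",
             _to_str(_mutate(base, rng, cfg.p_snp, cfg.p_indel, cfg.indel_mean)))
            for i in range(cfg.n_refs)]
    seqs = [(f"seq{i + 1}",
             _to_str(_mutate(base, rng, cfg.p_snp, cfg.p_indel, cfg.indel_mean)))
            for i in range(cfg.n_seqs)]
    return refs, seqs


def sweep_references(seqs: Sequence[tuple[str, str]],
                     refs: Sequence[tuple[str, str]],
                     cfg: FactorizerConfig | None = None,
                     max_refs: int | None = None) -> pd.DataFrame:
    """Mean optimal RME count against the first n references, n = 1..max_refs.

    The mechanism behind the decaying curves: every factorization against a
    reference subset is also valid against a superset, and the greedy parse
    is minimal, so the mean count is monotone non-increasing in n.
    """
    cfg = cfg or FactorizerConfig()
    max_refs = len(refs) if max_refs is None else max_refs
    if max_refs > len(refs):
        raise ValueError("max_refs exceeds the number of references")
    full = ReferenceSet(refs, cfg.index_kind, cfg.k)
    rows = []
    for n in range(1, max_refs + 1):
        sub = full.subset(n)
        counts = [len(factorize_optimal(s, sub, name)) for name, s in seqs]
        rows.append((n, float(np.mean(counts))))
    return pd.DataFrame(rows, columns=["n_refs", "mean_rmes"])


def fit_power_law(table) -> tuple[float, float, float]:
    """Least-squares fit of ``count = a * n^b`` on the log-log scale.

    Accepts the DataFrame from :func:`sweep_references` or an ``(x, y)``
    pair of arrays.  Returns ``(a, b, r2)`` with R^2 computed on the log
    scale; constant data yields ``b = 0`` and ``r2 = 1.0`` by convention
    (the fit is exact).
    """
    if isinstance(table, pd.DataFrame):
        x = table.iloc[:, 0].to_numpy(dtype=float)
        y = table.iloc[:, 1].to_numpy(dtype=float)
    else:
        x, y = table
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires positive values")
    lx, ly = np.log(x), np.log(y)
    b, la = np.polyfit(lx, ly, 1)
    resid = ly - (la + b * lx)
    ss_res = float(resid @ resid)
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return (float(np.exp(la)), float(b), float(r2))
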