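"""Stochastic assembly oracle for the mean-field network statistics.

Builds an explicit random A_f + B_f network: every A-type end group
bonds independently with probability p, the bonded A-ends are matched
uniformly at random to an equal number of B-ends, and the resulting
bipartite (multi)graph of macromers is analysed empirically.  At large
n the per-macromer bonded-arm distribution converges to Binomial(f, p)
and membership in the giant component reproduces the extinction
-probability (gel-connected) statistics, so this module is an
independent brute-force check on the closed-form elasticity math —
including the Flory-Stockmayer gel point at p = 1/(f-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ValidationError

__all__ = ["AssemblyResult", "assemble"]


@dataclass(frozen=True)
class AssemblyResult:
    """Empirical statistics of one assembled network realisation.

    Chain/junction counts use the active-network convention: macromers
    with >= 3 bonded arms are junctions, each of their bonded arms is
    half a chain.  ``gel_*`` statistics restrict to macromers in the
    largest connected component (the finite-size giant component).
    """

    n_macromers: int                 # total, both species
    seed: int
    p: float
    functionality: int
    bonded_arm_fractions: tuple[float, ...]   # fraction with i bonded arms
    gel_arm_fractions: tuple[float, ...]      # as above, but 0 unless in giant comp.
    mean_chains_per_macromer: float
    mean_junctions_per_macromer: float
    se_chains_per_macromer: float
    se_junctions_per_macromer: float
    gel_fraction: float


def assemble(n_a: int, n_b: int, f: int = 4, p: float = 0.5,
             seed: int = 0) -> AssemblyResult:
    """Assemble one random network realisation and measure it.

    Requires stoichiometric mixing (``n_a == n_b``).  Deterministic for
    a fixed seed.
    """
    if n_a != n_b:
        raise ValidationError("stoichiometric assembly requires n_a == n_b")
    if n_a < 1 or f < 3:
        raise ValidationError("need n_a >= 1 and f >= 3")
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p!r}")

    rng = np.random.default_rng(seed)
    n_ends = n_a * f
    a_bonded = np.flatnonzero(rng.random(n_ends) < p)
    k = a_bonded.size
    b_bonded = rng.choice(n_ends, size=k, replace=False)

    a_macro = a_bonded // f                 # 0 .. n_a-1
    b_macro = b_bonded // f + n_a           # n_a .. 2n_a-1
    n_total = n_a + n_b

    counts = np.bincount(a_macro, minlength=n_total) + \
        np.bincount(b_macro, minlength=n_total)

    if k:
        adj = coo_matrix((np.ones(k, dtype=np.int8), (a_macro, b_macro)),
                         shape=(n_total, n_total))
        n_comp, labels = connected_components(adj, directed=False)
        comp_sizes = np.bincount(labels)
        giant = int(np.argmax(comp_sizes))
        in_giant = labels == giant
        gel_fraction = float(comp_sizes[giant]) / n_total
    else:
        in_giant = np.zeros(n_total, dtype=bool)
        gel_fraction = 0.0

    bonded_hist = np.bincount(counts, minlength=f + 1)[: f + 1] / n_total
    gel_counts = np.where(in_giant, counts, 0)
    gel_hist = np.bincount(gel_counts, minlength=f + 1)[: f + 1] / n_total

    chains = np.where(counts >= 3, counts / 2.0, 0.0)
    junctions = (counts >= 3).astype(float)
    return AssemblyResult(
        n_macromers=n_total, seed=seed, p=p, functionality=f,
        bonded_arm_fractions=tuple(bonded_hist.tolist()),
        gel_arm_fractions=tuple(gel_hist.tolist()),
        mean_chains_per_macromer=float(chains.mean()),
        mean_junctions_per_macromer=float(junctions.mean()),
        se_chains_per_macromer=float(chains.std(ddof=1) / np.sqrt(n_total)),
        se_junctions_per_macromer=float(junctions.std(ddof=1) / np.sqrt(n_total)),
        gel_fraction=gel_fraction,
    )
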