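"""Markov diffusion of the initial signal through tissue transition matrices.

The signal vector S is treated as a row vector and propagated through a
row-stochastic transition matrix P one step at a time, S_t = S_{t-1} P.
Because P is row-stochastic the total signal mass is conserved at every step;
diffusion only redistributes it along the tissue-weighted network. Iteration
stops when the relative L1 change between consecutive steps falls below a
tolerance (default 1e-3), typically after a handful of steps.

No restart/teleport term is used by default: the model is plain power
iteration with a stopping rule, which reaches a stable profile at a small
finite diffusion time. A restart probability can be supplied for sensitivity
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .interactome import TissueTransitionMatrix

logger = logging.getLogger(__name__)

__all__ = ["DiffusionProfile", "diffuse", "diffuse_until_converged",
           "diffuse_all_tissues"]

DEFAULT_TOL = 1e-3
DEFAULT_MAX_T = 200


@dataclass(frozen=True)
class DiffusionProfile:
    """Converged diffusion result for one tissue."""

    tissue: str
    signal: pd.Series            # diffused intensity per gene
    t: int                       # steps taken to converge
    trace: tuple[float, ...]     # relative L1 change at each step
    converged: bool = True


def _as_array(s0, genes: tuple[str, ...]) -> np.ndarray:
    if isinstance(s0, pd.Series):
        if tuple(s0.index) != genes:
            missing = set(genes) ^ set(s0.index)
            if missing:
                raise ValueError(
                    f"signal vector and transition matrix gene indices differ "
                    f"(e.g. {sorted(missing)[:3]})"
                )
            s0 = s0.reindex(list(genes))
        arr = s0.to_numpy(dtype=float)
    else:
        arr = np.asarray(s0, dtype=float)
    if arr.shape != (len(genes),):
        raise ValueError(
            f"signal length {arr.shape} does not match {len(genes)} genes"
        )
    if (arr < 0).any():
        raise ValueError("initial signal must be non-negative")
    return arr


def diffuse(
    s0,
    p: TissueTransitionMatrix,
    t: int,
    restart: float = 0.0,
) -> pd.Series:
    """Propagate the signal exactly ``t`` steps: S_t = S_0 P^t.

    With ``restart`` > 0 each step mixes back a fraction of the initial
    signal: S_k = (1 - restart) S_{k-1} P + restart S_0.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if not 0.0 <= restart < 1.0:
        raise ValueError("restart must be in [0, 1)")
    s_init = _as_array(s0, p.genes)
    s = s_init.copy()
    for _ in range(t):
        s = (1.0 - restart) * (s @ p.matrix) + restart * s_init
    return pd.Series(s, index=list(p.genes), name=p.tissue)


def diffuse_until_converged(
    s0,
    p: TissueTransitionMatrix,
    tol: float = DEFAULT_TOL,
    max_t: int = DEFAULT_MAX_T,
    restart: float = 0.0,
) -> DiffusionProfile:
    """Iterate single steps until the relative L1 change drops below ``tol``.

    Stops at the first t with ||S_t - S_{t-1}||_1 / ||S_{t-1}||_1 < tol, or at
    ``max_t`` with a logged warning and ``converged=False``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_t < 1:
        raise ValueError("max_t must be >= 1")
    s_init = _as_array(s0, p.genes)
    if s_init.sum() == 0:
        raise ValueError("zero initial signal mass: nothing to diffuse")
    s_prev = s_init.copy()
    trace: list[float] = []
    t = 0
    converged = False
    while t < max_t:
        t += 1
        s = (1.0 - restart) * (s_prev @ p.matrix) + restart * s_init
        change = float(np.abs(s - s_prev).sum() / np.abs(s_prev).sum())
        trace.append(change)
        s_prev = s
        if change < tol:
            converged = True
            break
    if not converged:
        logger.warning("tissue %s: diffusion did not converge in %d steps "
                       "(last change %.3g)", p.tissue, max_t, trace[-1])
    return DiffusionProfile(
        tissue=p.tissue,
        signal=pd.Series(s_prev, index=list(p.genes), name=p.tissue),
        t=t,
        trace=tuple(trace),
        converged=converged,
    )


def diffuse_all_tissues(
    s0,
    matrices: Mapping[str, TissueTransitionMatrix],
    tol: float = DEFAULT_TOL,
    max_t: int = DEFAULT_MAX_T,
    restart: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, DiffusionProfile]]:
    """Diffuse to convergence in every tissue; assemble gene x tissue intensities.

    Returns the intensity matrix (one column per tissue, aligned rows) and the
    per-tissue :class:`DiffusionProfile` with convergence diagnostics.
    """
    if not matrices:
        raise ValueError("no transition matrices supplied")
    gene_indices = {tuple(m.genes) for m in matrices.values()}
    if len(gene_indices) != 1:
        raise ValueError("transition matrices do not share a gene index")
    profiles: dict[str, DiffusionProfile] = {}
    columns = {}
    for tissue, p in matrices.items():
        try:
            prof = diffuse_until_converged(s0, p, tol=tol, max_t=max_t,
                                           restart=restart)
        except ValueError as err:
            raise ValueError(f"tissue {tissue!r}: {err}") from err
        profiles[tissue] = prof
        columns[tissue] = prof.signal
    intensity = pd.DataFrame(columns)
    return intensity, profiles
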