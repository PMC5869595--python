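"""Exact transition-matrix reference for the no-ATP dynamics.

Without ATP the model is a Markov chain on the state space
{unbound} + {bound at site i, i = 0..n-1} for a single motor on one DNA
molecule.  This module builds that (n+1) x (n+1) row-stochastic matrix with
exactly the engine's one-MCS semantics (uniform candidate binding accepted
with p_on(site type); unbinding with p_off(site type); otherwise one
sliding step from the shared discretised kernel with boundary reflection
and capture at the first SRS site scanned)
and solves for its stationary distribution.  It is the independent
correctness gate for the simulator's Markov rules.
"""

from __future__ import annotations

import numpy as np

from .kernels import (slide_destinations, slide_magnitude_pmf,
                      srs_neighbor_tables)
from .params import ModelParams
from .substrate import SubstrateSpec

MAX_ORACLE_SITES = 200


def transition_matrix(spec: SubstrateSpec, params: ModelParams) -> np.ndarray:
    """One-MCS transition matrix of the single-motor no-ATP chain.

    State 0 is unbound; state 1 + i is bound at site i.  Rows sum to 1.
    """
    n = spec.length_bp
    if n > MAX_ORACLE_SITES:
        raise ValueError(f"oracle limited to {MAX_ORACLE_SITES} sites, "
                         f"got {n}")
    is_srs = spec.is_srs_array()
    p_on = np.where(is_srs, params.p_on_srs, params.p_on_ns)
    p_off = np.where(is_srs, params.p_off_srs, params.p_off_ns)
    mags_ns, pmf_ns = slide_magnitude_pmf(params.sld_ns_mean, params.sld_ns_sd)
    mags_srs, pmf_srs = slide_magnitude_pmf(params.sld_srs_mean,
                                            params.sld_srs_sd)

    if is_srs.any():
        next_left, next_right = srs_neighbor_tables(is_srs)
    else:
        next_left = next_right = None

    P = np.zeros((n + 1, n + 1))
    # unbound row: uniform candidate site, acceptance p_on(site)
    P[0, 1:] = p_on / n
    P[0, 0] = 1.0 - P[0, 1:].sum()

    for i in range(n):
        row = P[1 + i]
        row[0] = p_off[i]
        stay_mass = 1.0 - p_off[i]
        mags, pmf = (mags_srs, pmf_srs) if is_srs[i] else (mags_ns, pmf_ns)
        start = np.full(mags.size, i)
        left = slide_destinations(start, -mags, n, next_left, next_right)
        right = slide_destinations(start, mags, n, next_left, next_right)
        np.add.at(row, 1 + left, stay_mass * 0.5 * pmf)
        np.add.at(row, 1 + right, stay_mass * 0.5 * pmf)
    return P


def stationary_distribution(P: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Left eigenvector of P for eigenvalue 1, normalized to a probability
    vector; raises if the residual ||pi P - pi||_inf exceeds ``tol``."""
    m = P.shape[0]
    # solve pi (P - I) = 0 with the normalization constraint appended
    A = np.vstack([P.T - np.eye(m), np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = np.abs(pi @ P - pi).max()
    if residual > tol:
        raise RuntimeError(f"stationary solve did not converge "
                           f"(residual {residual:.2e})")
    return pi


def stationary_bound_profile(spec: SubstrateSpec,
                             params: ModelParams) -> np.ndarray:
    """Stationary site-occupancy profile conditional on being bound."""
    pi = stationary_distribution(transition_matrix(spec, params))
    bound = pi[1:]
    return bound / bound.sum()


def no_sliding_srs_occupancy(spec: SubstrateSpec,
                             params: ModelParams) -> float:
    """Closed-form SRS occupancy of the no-sliding chain.

    Each site is an independent two-state (empty/bound) chain, so the
    stationary bound mass at site i is proportional to p_on(i)/p_off(i):

        occ = n_SRS k_SRS / (n_SRS k_SRS + n_NS k_NS),  k = p_on/p_off.
    """
    n = spec.length_bp
    n_srs = int(spec.is_srs_array().sum())
    n_ns = n - n_srs
    k_srs = params.p_on_srs / params.p_off_srs
    k_ns = params.p_on_ns / params.p_off_ns
    return n_srs * k_srs / (n_srs * k_srs + n_ns * k_ns)
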