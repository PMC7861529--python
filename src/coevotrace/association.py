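"""Association statistics: from raw pair z-scores to direct couplings.

Pseudo-correlations rescale the ordered-sum z-scores into [-1, 1].
Shrinkage partial correlations then separate direct couplings from
indirect ones transmitted through third sites; the composite association
statistic keeps the partial correlation (clipped at zero) for positively
pseudo-correlated pairs and the pseudo-correlation itself for negative
ones.  Two further per-pair measures probe the cause of the signal: the
clustering z-score of non-consecutive substitutions (episodic selection
clusters all substitutions, epistasis only consecutive ones) and the
mutual allele preference (MAP), which asks whether the identity of the
derived allele at a trailing site depends on the derived allele that
previously arose at the leading site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epistat import NullSampler
from .phylo import SubstitutionHistory, ValidationError


def pseudo_correlations(z: np.ndarray) -> np.ndarray:
    """Rescale z-scores by the global maximum absolute value into [-1, 1]."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        return z.copy()
    m = np.nanmax(np.abs(z))
    return z / m if m > 0 else np.zeros_like(z)


def partial_correlations(rho_matrix: np.ndarray, lam: float = 0.9) -> np.ndarray:
    """Shrinkage partial correlations (corpcor-style).

    The correlation matrix is shrunk toward the identity, C* = lam*I +
    (1 - lam)*C, inverted, and the precision matrix scaled into partial
    correlations p_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj); the
    diagonal is reported as 1.
    """
    C = np.asarray(rho_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValidationError("correlation matrix must be symmetric")
    if not 0.0 <= lam < 1.0:
        raise ValueError("shrinkage intensity must lie in [0, 1)")
    n = C.shape[0]
    shrunk = lam * np.eye(n) + (1.0 - lam) * C
    # a pseudo-correlation matrix need not be positive definite; step the
    # shrinkage toward the identity until the inverse is well defined
    eff = lam
    while np.linalg.eigvalsh(shrunk)[0] <= 1e-10 and eff < 1.0 - 1e-6:
        eff = 1.0 - (1.0 - eff) / 2.0
        shrunk = eff * np.eye(n) + (1.0 - eff) * C
    omega = np.linalg.inv(shrunk)
    d = np.sqrt(np.diag(omega))
    partial = -omega / np.outer(d, d)
    np.fill_diagonal(partial, 1.0)
    return partial


def association_statistics(rho: np.ndarray, partial: np.ndarray) -> np.ndarray:
    """Composite association statistic per pair.

    Positive pseudo-correlation: the partial correlation if positive, else
    zero.  Negative pseudo-correlation: the pseudo-correlation itself.
    Zero: zero.
    """
    rho = np.asarray(rho, dtype=float)
    partial = np.asarray(partial, dtype=float)
    if rho.shape != partial.shape:
        raise ValidationError("pseudo- and partial-correlation arrays misaligned")
    return np.where(rho > 0, np.maximum(partial, 0.0), np.where(rho < 0, rho, 0.0))


# ---------------------------------------------------------------------------
# clustering of non-consecutive substitutions


def _mean_noncons_distance(tree, branches_a, branches_b, same_branch_pairs=True):
    """Mean midpoint distance over non-consecutive cross-site event pairs.

    Works directly on branch sets; consecutive pairs are re-derived with
    the nearest-event rule so that rewired replicates are scored exactly
    like the data.  Returns (mean, count); mean is NaN when count is 0.
    """
    set_a = set(int(b) for b in branches_a)
    set_b = set(int(b) for b in branches_b)
    cons = set()

    def collect(lead_set, trail_set, flip):
        for tb in trail_set:
            v = tb
            found = None
            while v >= 0:
                if v == tb:
                    if same_branch_pairs and v in lead_set:
                        found = v
                        break
                else:
                    if v in lead_set:
                        found = v
                        break
                    if v in trail_set:
                        break
                v = tree.parent[v]
            if found is not None:
                cons.add((tb, found) if flip else (found, tb))

    collect(set_a, set_b, flip=False)
    collect(set_b, set_a, flip=True)
    total, count = 0.0, 0
    for ba in set_a:
        for bb in set_b:
            if (ba, bb) in cons:
                continue
            total += tree.midpoint_distance(ba, bb)
            count += 1
    return (total / count if count else float("nan")), count


@dataclass
class ClusteringResult:
    observed_mean: float
    null_mean: float
    null_sd: float
    z: float            # positive when substitutions are closer than expected
    p_upper: float      # clustering
    p_lower: float      # repulsion
    n_pairs: int


def clustering_zscore(
    history: SubstitutionHistory,
    site_a: int,
    site_b: int,
    n_null: int = 200,
    seed: int = 0,
) -> ClusteringResult:
    """Attraction of non-consecutive substitutions at one site pair.

    The statistic is the mean phylogenetic distance between all
    non-consecutive cross-site substitution pairs; the z-score is sign-
    inverted (null mean minus observed over the null sd) so that positive
    values mean the substitutions sit closer on the tree than the
    margin-preserving null expects.
    """
    tree = history.tree
    obs_a = [ev.branch for ev in history.events_at(site_a)]
    obs_b = [ev.branch for ev in history.events_at(site_b)]
    obs, n_obs = _mean_noncons_distance(
        tree, obs_a, obs_b, history.same_branch_pairs
    )
    if n_obs == 0:
        raise ValidationError("no non-consecutive pairs observed; statistic undefined")
    sites = history.analyzed_sites
    ia, ib = sites.index(site_a), sites.index(site_b)
    sampler = NullSampler(history, sites, seed=seed)
    null = np.empty(n_null)
    for r in range(n_null):
        rows, _ = next(sampler)
        null[r], _ = _mean_noncons_distance(
            tree, rows[ia], rows[ib], history.same_branch_pairs
        )
    null = null[~np.isnan(null)]
    mean, sd = float(null.mean()), float(null.std())
    z = 0.0 if sd == 0 else (mean - obs) / sd
    n = len(null)
    p_upper = (np.sum(null >= obs) + 1.0) / (n + 1.0)   # repulsion tail
    p_lower = (np.sum(null <= obs) + 1.0) / (n + 1.0)
    # clustering means observed BELOW null: upper p for clustering is the
    # probability of a null mean as small as observed
    return ClusteringResult(
        observed_mean=obs,
        null_mean=mean,
        null_sd=sd,
        z=float(z),
        p_upper=float(p_lower),
        p_lower=float(p_upper),
        n_pairs=n_obs,
    )


# ---------------------------------------------------------------------------
# mutual allele preference


def map_statistic(
    history: SubstitutionHistory, leading_site: int, trailing_site: int
) -> float | None:
    """Mutual allele preference, averaged over defined allele combinations.

    A trailing substitution qualifies when at least one leading-site
    substitution lies strictly on its root path; the most recent such
    substitution provides the background derived allele A.  For every
    combination (A, b, B) of background allele, trailing ancestral allele
    and trailing derived allele satisfying the positivity constraints,

        M = P(s1>A) * P(B | A background, b at s2)
            + P(s1>!A) * P(!B | !A background, b at s2)

    where P(s1>A) is the fraction of leading substitutions producing A.
    Returns the mean of M over defined combinations, or None when no
    combination is defined (distinct from 0).
    """
    tree = history.tree
    lead_events = history.events_at(leading_site)
    trail_events = history.events_at(trailing_site)
    if not lead_events or not trail_events:
        return None
    lead_by_branch = {ev.branch: ev for ev in lead_events}
    level = tree.level

    # qualified trailing events with their background allele
    qualified = []  # (A_background, b_ancestral, B_derived)
    for tev in trail_events:
        v = tree.parent[tev.branch]
        best = None
        while v >= 0:
            if v in lead_by_branch:
                best = lead_by_branch[v]
                break
            v = tree.parent[v]
        if best is not None:
            qualified.append((best.derived, tev.ancestral, tev.derived))

    if not qualified:
        return None

    n_lead = len(lead_events)
    lead_counts = {}
    for ev in lead_events:
        lead_counts[ev.derived] = lead_counts.get(ev.derived, 0) + 1

    values = []
    for A, b, B in sorted(set(qualified)):
        sub = [q for q in qualified if q[1] == b]
        n_b = len(sub)
        n_Ab = sum(1 for q in sub if q[0] == A)
        n_bB = sum(1 for q in sub if q[2] == B)
        n_AbB = sum(1 for q in sub if q[0] == A and q[2] == B)
        # positivity constraints: both backgrounds and both outcomes must
        # occur among the trailing substitutions from b; the combination
        # itself must be observed
        if n_Ab == 0 or n_b - n_Ab == 0 or n_bB == 0 or n_b - n_bB == 0:
            continue
        p_A = lead_counts.get(A, 0) / n_lead
        p_B_given_A = n_AbB / n_Ab
        p_notB_given_notA = 1.0 - (n_bB - n_AbB) / (n_b - n_Ab)
        values.append(p_A * p_B_given_A + (1.0 - p_A) * p_notB_given_notA)
    if not values:
        return None
    return float(np.mean(values))
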