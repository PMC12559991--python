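"""Copy-number / rate-constant trade-off that preserves mean tether numbers.

At a fixed gap ``d`` each tether copy binds independently, so the long-term
mean number of formed tethers of a species is

    n̄(d) = n_total · k_on(d) / (k_off + k_on(d)).

Scaling the copy number by α > 0 can be compensated exactly by

    k_on′  = k_on / α,
    k_off′ = k_off + (α − 1) · k_on / α,

the unique pair with k_on′ = k_on/α satisfying
``mean(α·n_total, k_on′, k_off′) = mean(n_total, k_on, k_off)`` at every
``d`` where the compensation is applied at a common k_on (here: at the
profile maximum, g_on = 1, i.e. at the level of k_on,max).  The transform is
valid only for α > k_on/(k_off + k_on); below that bound the compensated
dissociation rate would be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidSpecError

__all__ = ["RescalePlan", "mean_tethers", "rescale_rates"]


@dataclass(frozen=True)
class RescalePlan:
    """A copy-number rescaling and its mean-preserving rate compensation."""

    alpha: float
    base_kon: float
    base_koff: float
    rescaled_kon: float
    rescaled_koff: float


def mean_tethers(n_total: float, kon: float, koff: float) -> float:
    """Steady-state mean number of formed tethers, n_total·k_on/(k_off + k_on)."""
    if kon < 0 or koff < 0:
        raise InvalidSpecError("rates must be non-negative")
    if kon == 0 and koff == 0:
        raise InvalidSpecError("kon and koff cannot both be zero")
    return n_total * kon / (koff + kon)


def rescale_rates(base_kon: float, base_koff: float, alpha: float) -> RescalePlan:
    """Compensating rates for an α-fold change in copy number.

    Raises
    ------
    InvalidSpecError
        If α is at or below the validity bound k_on/(k_off + k_on), where the
        compensated dissociation rate stops being positive.
    """
    if alpha <= 0:
        raise InvalidSpecError("alpha must be positive")
    bound = base_kon / (base_koff + base_kon)
    if alpha <= bound:
        raise InvalidSpecError(
            f"alpha={alpha} is at/below the validity bound {bound:.6g}; "
            "the compensated dissociation rate would be negative")
    kon_new = base_kon / alpha
    koff_new = base_koff + (alpha - 1.0) * base_kon / alpha
    plan = RescalePlan(alpha, base_kon, base_koff, kon_new, koff_new)
    # mean preservation must hold identically; verify before returning
    base_mean = mean_tethers(1.0, base_kon, base_koff)
    new_mean = mean_tethers(alpha, kon_new, koff_new)
    if abs(new_mean - base_mean) > 1e-12 * max(abs(base_mean), 1.0):
        raise AssertionError("mean-preservation identity violated")
    return plan
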