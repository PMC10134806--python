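"""Growth-rate-dependent FBA: a fixed point between composition and growth.

The biomass reaction encodes a composition measured at one growth rate, but
composition itself shifts with growth rate.  Growth-rate-dependent FBA
closes the loop: guess a growth rate, rebuild the biomass reaction for the
composition at that rate, run FBA, feed the predicted growth rate back in,
and iterate until input and output growth rates agree.  Because composition
varies slowly with growth rate the map is a mild contraction and plain
fixed-point iteration converges in a handful of steps, independent of the
initial guess.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

from .composition import (
    BiomassComposition,
    GrowthRateFits,
    MonomerProfile,
    OsmolyteSpec,
    ReferenceRemainder,
    build_biomass_reaction,
    composition_at,
)
from .model_core import (
    FluxSolution,
    FluxStatus,
    MetabolicModel,
    ModelError,
    Reaction,
    fba,
    set_medium,
)

__all__ = ["GrFbaResult", "FluxComparison", "gr_fba", "flux_compare", "composition_biomass_builder"]

#: Fluxes below this magnitude are treated as zero when comparing solutions.
ZERO_FLUX = 1e-9


@dataclass(frozen=True)
class GrFbaResult:
    fixed_point_gr: float
    iterations: int
    converged: bool
    trajectory: Tuple[float, ...]
    solution: FluxSolution


@dataclass(frozen=True)
class FluxComparison:
    per_reaction: Mapping[str, float]  # percent difference per reaction
    fraction_over_threshold: float  # share of reactions differing >= threshold
    threshold: float = 20.0


def composition_biomass_builder(
    fits: GrowthRateFits,
    profiles: Sequence[MonomerProfile],
    osmo: OsmolyteSpec = OsmolyteSpec(),
    remainder: Optional[ReferenceRemainder] = None,
    gam: float = 0.0,
    **biomass_kwargs,
) -> Callable[[float], Reaction]:
    """Builder mapping a growth rate to its composition's biomass reaction."""

    def build(gr: float) -> Reaction:
        comp = composition_at(gr, fits, osmo, remainder, gam=gam)
        return build_biomass_reaction(comp, profiles, **biomass_kwargs)

    return build


def gr_fba(
    model: MetabolicModel,
    biomass_builder: Callable[[float], Reaction],
    medium: Mapping[str, Tuple[float, float]],
    gr0: float,
    tol: float = 1e-4,
    max_iter: int = 50,
    damping: float = 0.0,
    biomass_id: str = "BIOMASS",
) -> GrFbaResult:
    """Iterate gr -> FBA-optimal growth of the model rebuilt at gr.

    Stops when successive growth rates differ by less than ``tol`` (1/h) or
    after ``max_iter`` iterations (``converged=False``).  ``damping`` blends
    the update as (1-d)*new + d*old; zero by default, useful only if the
    iteration oscillates.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not (0 <= damping < 1):
        raise ValueError("damping must be in [0, 1)")
    base = set_medium(model, medium)
    gr = float(gr0)
    trajectory: List[float] = [gr]
    solution: Optional[FluxSolution] = None
    converged = False
    for it in range(1, max_iter + 1):
        m = base.copy()
        new_bio = biomass_builder(gr)
        idx = next(i for i, r in enumerate(m.reactions) if r.id == biomass_id)
        m.reactions[idx] = Reaction(
            id=biomass_id,
            stoichiometry=dict(new_bio.stoichiometry),
            lower_bound=m.reactions[idx].lower_bound,
            upper_bound=m.reactions[idx].upper_bound,
        )
        m.validate()
        sol = fba(m)
        if sol.status is not FluxStatus.OPTIMAL:
            raise ModelError(f"FBA {sol.status.value} at iteration {it} (gr={gr:.4g})")
        gr_new = (1.0 - damping) * sol.objective_value + damping * gr
        trajectory.append(gr_new)
        solution = sol
        if abs(gr_new - gr) < tol:
            gr = gr_new
            converged = True
            break
        gr = gr_new
    assert solution is not None
    return GrFbaResult(
        fixed_point_gr=gr,
        iterations=len(trajectory) - 1,
        converged=converged,
        trajectory=tuple(trajectory),
        solution=solution,
    )


def flux_compare(a: FluxSolution, b: FluxSolution, threshold: float = 20.0) -> FluxComparison:
    """Percent difference per reaction between two flux solutions.

    Per reaction: 100*|va - vb| / max(|va|, |vb|), defined as 0 when both
    magnitudes are below 1e-9.  Individual optimal fluxes are generally not
    unique; only summary shares (the fraction differing by at least the
    threshold) are meaningful quantities.
    """
    if set(a.fluxes) != set(b.fluxes):
        raise ValueError("flux solutions cover different reaction sets")
    per: Dict[str, float] = {}
    for rid, va in a.fluxes.items():
        vb = b.fluxes[rid]
        denom = max(abs(va), abs(vb))
        per[rid] = 0.0 if denom < ZERO_FLUX else 100.0 * abs(va - vb) / denom
    n = len(per)
    frac = sum(1 for d in per.values() if d >= threshold) / n if n else 0.0
    return FluxComparison(per_reaction=per, fraction_over_threshold=frac, threshold=threshold)
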