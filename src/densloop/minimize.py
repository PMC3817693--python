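"""Whole-structure Cartesian minimization of the low-resolution objective.

Instead of closing chain breaks geometrically, the minimization route lets
the *entire* structure relax under the smooth low-resolution energy: the
bond-geometry restraints pull open junctions closed while Ramachandran,
hydrogen-bond, repulsion and density terms keep the rest of the backbone
sensible.  Because every term is differentiable with analytic Cartesian
gradients, a quasi-Newton optimiser (L-BFGS-B) can take large, concerted
backbone moves — the property that lets template regions drift away from
their starting conformation when the density supports it.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import optimize

from .density import SplineScoreField
from .energy import EnergyModel
from .model import BackboneModel

logger = logging.getLogger(__name__)


def cartesian_minimize(model: BackboneModel, energy: EnergyModel,
                       field: SplineScoreField | None = None,
                       movable: np.ndarray | None = None,
                       max_evals: int = 2000, gtol: float = 1e-4,
                       on_empty: str = "error"):
    """Quasi-Newton descent on the Cartesian coordinates of movable residues.

    Parameters
    ----------
    movable : boolean per-residue mask; defaults to ``model.movable``.
        Frozen residues still contribute to the energy but their
        coordinates are never touched.
    on_empty : "error" or "noop" when the movable mask selects nothing.

    Returns ``(minimized_model, final_energy)``; the result's energy never
    exceeds the input energy, and torsions are re-synchronised from the
    final coordinates.
    """
    work = model.copy()
    mask = model.movable if movable is None else np.asarray(movable, bool)
    free = np.zeros(work.coords.shape, dtype=bool)
    free[mask] = True
    free &= np.isfinite(work.coords)
    if not free.any():
        if on_empty == "noop":
            e0, _ = _checked_energy(work, energy, field)
            return work, e0
        raise ValueError("movable mask selects no atoms")

    e0, g0 = _checked_energy(work, energy, field)
    x0 = work.coords[free]

    def objective(x):
        work.coords[free] = x
        e, g = energy.total_energy(work, field)
        return e, g[free]

    res = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxfun": int(max_evals), "gtol": gtol, "ftol": 1e-12,
                 "maxiter": int(max_evals)},
    )
    if res.fun <= e0:
        work.coords[free] = res.x
        final = float(res.fun)
    else:  # never return something worse than the input
        work.coords[free] = x0
        final = e0
    # break flags are re-derived from the final geometry (healed junctions
    # become bonded again; numbering gaps stay broken)
    work.break_after[:] = False
    work.detect_breaks()
    work.sync_torsions()
    return work, final


def _checked_energy(model, energy, field):
    try:
        return energy.total_energy(model, field)
    except FloatingPointError:
        # identify the offending term for the error message
        for name in EnergyModel.TERMS:
            if energy.weights.get(name, 0.0) == 0.0:
                continue
            fn = {"rama": energy.rama_energy, "vdw": energy.vdw_energy,
                  "hbond_bb": energy.hbond_bb_energy,
                  "cart_bonded": energy.cart_bonded_energy}.get(name)
            if fn is None:
                e, _ = energy.density_energy(model, field)
            else:
                e, _ = fn(model)
            if not np.isfinite(e):
                raise FloatingPointError(
                    f"non-finite starting energy in term {name!r}")
        raise


def heal_insertion(model: BackboneModel, inserted_window: tuple[int, int],
                   energy: EnergyModel, field: SplineScoreField | None = None,
                   max_evals: int = 400, bond_tol: float = 0.05):
    """Pull the junctions of a just-superposed fragment window closed by
    whole-structure minimization.

    All residues with coordinates are movable; the bond-geometry term (which
    must carry a nonzero weight) penalises the broken junctions and the
    minimiser heals them while the other terms keep the surroundings
    physical.  If the largest backbone bond-length deviation still exceeds
    ``bond_tol`` after the budget, the model is returned with its
    ``strained`` flag set.
    """
    if energy.weights.get("cart_bonded", 0.0) <= 0.0:
        raise ValueError("heal_insertion requires an active cart_bonded term")
    movable = np.array([model.has_coords(i) for i in range(model.n_res)])
    healed, final = cartesian_minimize(model, energy, field, movable=movable,
                                       max_evals=max_evals)
    devs = healed.bond_length_deviations()
    healed.strained = bool(len(devs) and devs.max() >= bond_tol)
    if healed.strained:
        logger.warning("heal_insertion: residual bond deviation %.3f A",
                       devs.max())
    return healed
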