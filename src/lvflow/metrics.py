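"""Reconstruction quality metrics: relative L2 errors, vorticity, and
global kinetic-energy discrepancies.

All norms are taken over inside-mask nodes only, unweighted by cell volume
(the grid spacing is uniform, so weighting would be a constant factor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import VelocityField
from .grid_ops import MaskedDomain, apply_masked

__all__ = [
    "relative_l2_error",
    "frame_relative_error",
    "vorticity",
    "energy_discrepancies",
    "ErrorReport",
]


def _masked_sq(v: VelocityField, domain: MaskedDomain) -> float:
    m = domain.inside
    return float(sum((v.v[i][m] ** 2).sum() for i in range(3)))


def _masked_diff_sq(a: VelocityField, b: VelocityField,
                    domain: MaskedDomain) -> float:
    m = domain.inside
    return float(sum(((a.v[i][m] - b.v[i][m]) ** 2).sum() for i in range(3)))


def relative_l2_error(
    v_r: list[VelocityField],
    v_f: list[VelocityField],
    domains: list[MaskedDomain],
    on_zero: str = "raise",
) -> float:
    """Cycle-aggregate relative L2 error
    sqrt(Σ_t ‖v_r − v_f‖²) / sqrt(Σ_t ‖v_f‖²) over inside nodes.

    A vanishing reference norm raises ``ZeroDivisionError`` by default;
    with ``on_zero="zero"`` an exactly matching zero pair reports 0.
    """
    if not len(v_r) == len(v_f) == len(domains):
        raise ValueError("series lengths differ")
    num = sum(_masked_diff_sq(a, b, d) for a, b, d in zip(v_r, v_f, domains))
    den = sum(_masked_sq(b, d) for b, d in zip(v_f, domains))
    if den == 0.0:
        if on_zero == "zero":
            return 0.0 if num == 0.0 else float("inf")
        raise ZeroDivisionError("reference field is identically zero")
    return float(np.sqrt(num / den))


def frame_relative_error(
    v_r: VelocityField, v_f: VelocityField, domain: MaskedDomain,
    on_zero: str = "raise",
) -> float:
    """Single-frame ‖v_r − v_f‖₂ / ‖v_f‖₂ over inside nodes."""
    return relative_l2_error([v_r], [v_f], [domain], on_zero=on_zero)


def vorticity(
    v: VelocityField, domain: MaskedDomain, scheme: str = "one_sided"
) -> VelocityField:
    """Discrete curl ω = ∇×v on the masked domain (zero outside)."""

    def d(op, comp):
        return apply_masked(op, v.v[comp], domain, scheme)

    w = np.stack(
        [
            d("dy", 2) - d("dz", 1),
            d("dz", 0) - d("dx", 2),
            d("dx", 1) - d("dy", 0),
        ]
    )
    return VelocityField(v.grid, w, frame_time=v.frame_time)


def energy_discrepancies(
    v_r: VelocityField,
    v_f: VelocityField,
    w_r: VelocityField,
    w_f: VelocityField,
    domain: MaskedDomain,
) -> tuple[float, float]:
    """Per-frame global energy discrepancies
    (Δk/k^f, Δk_ω/k_ω^f) = (| ‖v^f‖−‖v^r‖ | / ‖v^f‖, same for ω)."""
    kv_f = np.sqrt(_masked_sq(v_f, domain))
    kw_f = np.sqrt(_masked_sq(w_f, domain))
    if kv_f == 0.0 or kw_f == 0.0:
        raise ZeroDivisionError("reference velocity/vorticity norm is zero")
    kv_r = np.sqrt(_masked_sq(v_r, domain))
    kw_r = np.sqrt(_masked_sq(w_r, domain))
    return abs(kv_f - kv_r) / kv_f, abs(kw_f - kw_r) / kw_f


@dataclass
class ErrorReport:
    """Per-frame and cycle-aggregate reconstruction errors.

    Columns mirror the standard presentation: fractional phase t/T, the
    pointwise relative L2 errors of velocity and vorticity, and the global
    energy discrepancies of each.
    """

    t_over_T: np.ndarray
    velocity_error: np.ndarray
    vorticity_error: np.ndarray
    energy_discrepancy: np.ndarray
    vorticity_energy_discrepancy: np.ndarray
    cycle_velocity_error: float
    cycle_vorticity_error: float

    @classmethod
    def from_series(
        cls,
        v_r: list[VelocityField],
        v_f: list[VelocityField],
        domains: list[MaskedDomain],
        period: float,
    ) -> "ErrorReport":
        w_r = [vorticity(v, d) for v, d in zip(v_r, domains)]
        w_f = [vorticity(v, d) for v, d in zip(v_f, domains)]

        def safe_rel(num_sq: float, den_sq: float) -> float:
            # a zero reference with a zero mismatch counts as zero error
            if den_sq == 0.0:
                return 0.0 if num_sq == 0.0 else np.inf
            return float(np.sqrt(num_sq / den_sq))

        def safe_energy(a, b, d):
            ka = np.sqrt(_masked_sq(a, d))
            kb = np.sqrt(_masked_sq(b, d))
            if kb == 0.0:
                return 0.0 if ka == 0.0 else np.inf
            return abs(kb - ka) / kb

        rows = [
            (
                safe_rel(_masked_diff_sq(a, b, d), _masked_sq(b, d)),
                safe_rel(_masked_diff_sq(wa, wb, d), _masked_sq(wb, d)),
                safe_energy(a, b, d),
                safe_energy(wa, wb, d),
            )
            for a, b, wa, wb, d in zip(v_r, v_f, w_r, w_f, domains)
        ]
        arr = np.array(rows)
        return cls(
            t_over_T=np.array([v.frame_time for v in v_f]) / period,
            velocity_error=arr[:, 0],
            vorticity_error=arr[:, 1],
            energy_discrepancy=arr[:, 2],
            vorticity_energy_discrepancy=arr[:, 3],
            cycle_velocity_error=safe_rel(
                sum(_masked_diff_sq(a, b, d)
                    for a, b, d in zip(v_r, v_f, domains)),
                sum(_masked_sq(b, d) for b, d in zip(v_f, domains)),
            ),
            cycle_vorticity_error=safe_rel(
                sum(_masked_diff_sq(a, b, d)
                    for a, b, d in zip(w_r, w_f, domains)),
                sum(_masked_sq(b, d) for b, d in zip(w_f, domains)),
            ),
        )

    def to_dict(self) -> dict:
        return {
            "t_over_T": self.t_over_T.tolist(),
            "velocity_error": self.velocity_error.tolist(),
            "vorticity_error": self.vorticity_error.tolist(),
            "energy_discrepancy": self.energy_discrepancy.tolist(),
            "vorticity_energy_discrepancy":
                self.vorticity_energy_discrepancy.tolist(),
            "cycle_velocity_error": self.cycle_velocity_error,
            "cycle_vorticity_error": self.cycle_vorticity_error,
        }

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(
                [
                    "t_over_T",
                    "velocity_error",
                    "vorticity_error",
                    "energy_discrepancy",
                    "vorticity_energy_discrepancy",
                ]
            )
            for row in zip(
                self.t_over_T,
                self.velocity_error,
                self.vorticity_error,
                self.energy_discrepancy,
                self.vorticity_energy_discrepancy,
            ):
                wr.writerow([f"{x:.6g}" for x in row])
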