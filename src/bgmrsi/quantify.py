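"""Conversion of fitted peak areas to institutional units (IU).

A fitted area is divided by the acquisition's relaxation attenuation

    F = exp(-TE/T2) * (1 - exp(-TR/T1))

and by the number of protons contributing to the peak (3 for NAA and
creatine, 9 for choline), then multiplied by an arbitrary global scale.
The resulting IU values are proportional to molecular concentrations
within a protocol; the global scale (default 1) is not meaningful across
protocols, which is what "institutional" signifies.
"""

from __future__ import annotations

import numpy as np

from .params import AcquisitionParams
from .presets import N_PROTONS, RelaxationParams


def relaxation_factor(
    metabolite: str,
    relax: dict[str, RelaxationParams],
    params: AcquisitionParams,
) -> float:
    """Relaxation attenuation F for one metabolite; corrected = raw / F."""
    if params.tr_ms <= 0 or params.te_ms < 0:
        raise ValueError("TR must be positive and TE non-negative")
    try:
        r = relax[metabolite]
    except KeyError:
        raise KeyError(f"no relaxation values for metabolite {metabolite!r}") from None
    return float(
        np.exp(-params.te_ms / r.t2_ms) * (1.0 - np.exp(-params.tr_ms / r.t1_ms))
    )


def to_institutional_units(
    area: float,
    metabolite: str,
    relax: dict[str, RelaxationParams],
    params: AcquisitionParams,
    scale: float = 1.0,
) -> float:
    """IU = scale * area / (F * n_protons)."""
    if area < 0:
        raise ValueError("peak area must be non-negative")
    try:
        protons = N_PROTONS[metabolite]
    except KeyError:
        raise KeyError(f"unknown metabolite {metabolite!r}") from None
    f = relaxation_factor(metabolite, relax, params)
    return scale * area / (f * protons)


def ratios(
    levels: dict[str, float], areas: dict[str, float]
) -> dict[str, float | None]:
    """IU-based and raw-area-based metabolite ratios for one voxel.

    Both families are reported: IU ratios compare relaxation- and
    proton-corrected levels; area ratios of the uncorrected fit areas are
    the quantity older studies tabulate.  Zero denominators yield None.
    """
    def q(num, den):
        return num / den if den and den > 0 else None

    return {
        "naa_cre": q(levels.get("NAA"), levels.get("Cre")),
        "cho_cre": q(levels.get("Cho"), levels.get("Cre")),
        "naa_cho": q(levels.get("NAA"), levels.get("Cho")),
        "area_naa_cre": q(areas.get("NAA"), areas.get("Cre")),
        "area_cho_cre": q(areas.get("Cho"), areas.get("Cre")),
        "area_naa_cho": q(areas.get("NAA"), areas.get("Cho")),
    }
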