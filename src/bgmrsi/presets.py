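"""Metabolite prior knowledge: chemical shifts, proton counts, relaxation
times and pure-tissue concentration presets.

Chemical shifts are the standard in-vivo proton positions: choline
(trimethylamine) 3.20 ppm, creatine (methyl) 3.03 ppm, NAA (acetyl)
2.02 ppm, and the lactate doublet centred at 1.31 ppm with a 7.3 Hz
splitting (inverted at TE = 145 ms, i.e. 1/J).

Concentrations are in institutional units (IU): a relative scale obtained
after T1/T2 relaxation correction and proton-count normalisation,
comparable within a protocol but not absolute molar values.
"""

from __future__ import annotations

from dataclasses import dataclass

METABOLITES = ("NAA", "Cho", "Cre", "Lac")

#: nominal chemical shift (ppm)
NOMINAL_PPM = {"Cho": 3.20, "Cre": 3.03, "NAA": 2.02, "Lac": 1.31}

#: J-splitting of the lactate methyl doublet at 1.5 T (Hz)
LACTATE_DOUBLET_HZ = 7.3

#: protons contributing to each fitted peak
N_PROTONS = {"NAA": 3, "Cre": 3, "Cho": 9, "Lac": 3}


@dataclass(frozen=True)
class RelaxationParams:
    """Longitudinal/transverse relaxation times for one metabolite."""

    t1_ms: float
    t2_ms: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("T1 and T2 must be positive")
        if self.t2_ms >= self.t1_ms:
            raise ValueError("expected T2 < T1")


#: Literature-style T1/T2 values appropriate to deep grey/white matter in
#: elderly subjects at 1.5 T.  The phantom generator uses the same preset,
#: so relaxation correction in `quantify` exactly inverts the simulated
#: signal weighting.
RELAXATION_PRESETS: dict[str, dict[str, RelaxationParams]] = {
    "basal_ganglia_elderly_1p5T": {
        "NAA": RelaxationParams(1450.0, 390.0, "basal_ganglia_elderly_1p5T"),
        "Cho": RelaxationParams(1150.0, 330.0, "basal_ganglia_elderly_1p5T"),
        "Cre": RelaxationParams(1550.0, 210.0, "basal_ganglia_elderly_1p5T"),
        "Lac": RelaxationParams(1550.0, 240.0, "basal_ganglia_elderly_1p5T"),
    },
}

#: Pure-tissue metabolite concentrations (IU) as (GM, WM) pairs.  The
#: "LBC1936" preset encodes the pure grey-/white-matter levels reported for
#: healthy adults in their early seventies at the level of the basal
#: ganglia: creatine higher in GM than WM, choline and NAA higher in WM.
#: Lactate is near zero in healthy brain; the fitting model nevertheless
#: retains its inverted doublet.
CONCENTRATION_PRESETS: dict[str, dict[str, tuple[float, float]]] = {
    "LBC1936": {
        "NAA": (70.0, 76.0),
        "Cho": (10.0, 13.0),
        "Cre": (57.0, 44.0),
        "Lac": (0.5, 0.5),
    },
}


def get_relaxation(preset: str = "basal_ganglia_elderly_1p5T") -> dict[str, RelaxationParams]:
    try:
        return dict(RELAXATION_PRESETS[preset])
    except KeyError:
        raise KeyError(f"unknown relaxation preset {preset!r}") from None


def get_concentrations(preset: str = "LBC1936") -> dict[str, tuple[float, float]]:
    try:
        return {m: tuple(v) for m, v in CONCENTRATION_PRESETS[preset].items()}
    except KeyError:
        raise KeyError(f"unknown concentration preset {preset!r}") from None
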