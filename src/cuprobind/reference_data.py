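"""Published reference measurements for NcLPMO9C inhibition.

Printed benchmark values used as pipeline inputs: specific activities of
the two photometric assays (coerulignone formation from hydrocoerulignone
or 2,6-DMP) at 100 mM inhibitor, turbidimetric rates on PASC, and fitted
IC50 values. Each entry carries the printed value, its reported
uncertainty and the resolution of the last printed digit, so downstream
comparisons can propagate the rounding of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Printed:
    """A printed number: value, reported uncertainty, print resolution."""

    value: float
    uncertainty: float
    resolution: float

    @property
    def half_ulp(self) -> float:
        return self.resolution / 2.0


#: Uninhibited specific activity in plain 100 mM acetate buffer, U g^-1.
REFERENCE_ACTIVITY = {
    "hydrocoerulignone": Printed(138.0, 12.0, 1.0),
    "2,6-DMP": Printed(23.0, 1.0, 1.0),
}

#: Specific activities with 100 mM inhibitor, U g^-1.
SPECIFIC_ACTIVITY = {
    "hydrocoerulignone": {
        "acetic acid": Printed(97.4, 7.2, 0.1),
        "lactic acid": Printed(67.6, 10.2, 0.1),
        "glyoxal": Printed(60.5, 4.9, 0.1),
        "pyruvic acid": Printed(5.6, 0.6, 0.1),
        "glyoxylic acid": Printed(1.5, 0.4, 0.1),
        "oxalic acid": Printed(0.8, 0.2, 0.1),
        "citric acid": Printed(2.0, 0.5, 0.1),
        "imidazole": Printed(99.4, 5.4, 0.1),
        "glycine": Printed(67.7, 1.6, 0.1),
        "histamine": Printed(2.2, 0.6, 0.1),
        "histidine": Printed(0.5, 0.3, 0.1),
    },
    "2,6-DMP": {
        "acetic acid": Printed(17.5, 1.5, 0.1),
        "lactic acid": Printed(6.4, 0.3, 0.1),
        "glyoxal": Printed(4.8, 0.3, 0.1),
        "pyruvic acid": Printed(0.1, 0.1, 0.1),
        "glyoxylic acid": Printed(0.1, 0.1, 0.1),
        "oxalic acid": Printed(0.1, 0.1, 0.1),
        "citric acid": Printed(0.3, 0.1, 0.1),
        "imidazole": Printed(18.3, 1.1, 0.1),
        "glycine": Printed(10.1, 0.8, 0.1),
        "histamine": Printed(0.8, 0.3, 0.1),
        "histidine": Printed(0.1, 0.1, 0.1),
    },
}

#: Residual activities as printed, percent of the buffer-only reference.
PRINTED_RESIDUAL = {
    "hydrocoerulignone": {
        "acetic acid": Printed(70.8, 5.2, 0.1),
        "lactic acid": Printed(49.2, 7.4, 0.1),
        "glyoxal": Printed(43.9, 3.6, 0.1),
        "pyruvic acid": Printed(4.1, 0.4, 0.1),
        "glyoxylic acid": Printed(1.1, 0.3, 0.1),
        "oxalic acid": Printed(0.6, 0.1, 0.1),
        "citric acid": Printed(1.5, 0.4, 0.1),
        "imidazole": Printed(72.2, 3.9, 0.1),
        "glycine": Printed(49.2, 1.2, 0.1),
        "histamine": Printed(1.6, 0.4, 0.1),
        "histidine": Printed(0.4, 0.2, 0.1),
    },
    "2,6-DMP": {
        "acetic acid": Printed(76.5, 6.6, 0.1),
        "lactic acid": Printed(28.1, 1.3, 0.1),
        "glyoxal": Printed(20.8, 1.5, 0.1),
        "pyruvic acid": Printed(0.1, 0.1, 0.1),
        "glyoxylic acid": Printed(0.1, 0.1, 0.1),
        "oxalic acid": Printed(0.1, 0.1, 0.1),
        "citric acid": Printed(1.3, 0.4, 0.1),
        "imidazole": Printed(80.0, 4.8, 0.1),
        "glycine": Printed(44.1, 3.5, 0.1),
        "histamine": Printed(3.5, 1.3, 0.1),
        "histidine": Printed(0.1, 0.1, 0.1),
    },
}

#: Turbidimetric rates (light intensity at 620 nm per minute) on PASC,
#: reference rate 0.17 +/- 0.02 in plain acetate buffer.
TURBIDITY_REFERENCE_RATE = Printed(0.17, 0.02, 0.01)

TURBIDITY_RATES = {
    "acetic acid": Printed(0.14, 0.01, 0.01),
    "phosphoric acid": Printed(0.107, 0.02, 0.001),
    "lactic acid": Printed(0.08, 0.02, 0.01),
    "citric acid": Printed(0.014, 0.001, 0.001),
    "oxalic acid": Printed(0.002, 0.001, 0.001),
}

TURBIDITY_PRINTED_RESIDUAL = {
    "acetic acid": Printed(84.0, 5.0, 1.0),
    "phosphoric acid": Printed(65.0, 10.0, 1.0),
    "lactic acid": Printed(47.0, 13.0, 1.0),
    "citric acid": Printed(8.0, 1.0, 1.0),
    "oxalic acid": Printed(1.4, 0.6, 0.1),
}

#: Fitted IC50 values, mM, per assay substrate.
IC50_TABLE = {
    "hydrocoerulignone": {
        "oxalic acid": Printed(1.1, 0.1, 0.1),
        "glyoxylic acid": Printed(7.1, 0.2, 0.1),
        "pyruvic acid": Printed(17.2, 1.0, 0.1),
        "citric acid": Printed(1.8, 0.3, 0.1),
        "histidine": Printed(1.0, 0.1, 0.1),
        "histamine": Printed(8.5, 0.4, 0.1),
        "glycine": Printed(115.0, 20.0, 1.0),
        "asparagine": Printed(24.9, 0.2, 0.1),
        "phenylalanine": Printed(23.8, 1.1, 0.1),
        "sodium sulfate": Printed(31.2, 4.7, 0.1),
        "sodium fluoride": Printed(142.0, 39.0, 1.0),
    },
    "2,6-DMP": {
        "oxalic acid": Printed(1.0, 0.1, 0.1),
        "glyoxylic acid": Printed(3.7, 0.6, 0.1),
        "pyruvic acid": Printed(12.4, 0.8, 0.1),
        "citric acid": Printed(2.7, 0.2, 0.1),
        "histidine": Printed(2.0, 0.1, 0.1),
        "histamine": Printed(16.3, 0.7, 0.1),
        "glycine": Printed(109.0, 6.0, 1.0),
        "asparagine": Printed(45.8, 2.8, 0.1),
        "phenylalanine": Printed(32.4, 3.7, 0.1),
        "sodium sulfate": Printed(32.8, 3.2, 0.1),
        "sodium fluoride": Printed(316.0, 17.0, 1.0),
    },
}

#: Potency orderings stated for the two analog families (most to least
#: active, i.e. weakest to strongest inhibitor).
OXALIC_ANALOG_ORDER = [
    "acetic acid", "lactic acid", "glyoxal",
    "pyruvic acid", "glyoxylic acid", "oxalic acid",
]
HISTIDINE_ANALOG_ORDER = ["imidazole", "glycine", "histamine", "histidine"]

#: Turbidimetric rate ordering (fastest to slowest).
TURBIDITY_ORDER = [
    "acetic acid", "phosphoric acid", "lactic acid", "citric acid", "oxalic acid",
]


def residual_tolerance(activity: Printed, reference: Printed, computed: float) -> float:
    """Comparison tolerance for a residual percentage computed from
    printed inputs: half a print unit on the output plus the propagated
    half-ulp rounding of the numerator and denominator."""
    rel = activity.half_ulp / activity.value + reference.half_ulp / reference.value
    return 0.05 + rel * abs(computed)
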