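"""Metabolite panels and reference concentration scales.

The default synthetic panel is a 30-metabolite subset of the compounds
quantified in bone marrow (BM) extracellular fluid and peripheral blood (PB)
plasma of pediatric acute lymphoblastic leukemia patients, with class labels
(lipid metabolism / amino acid / other, following Human Metabolome Database
style classification) and physiologically plausible plasma concentration
scales in μM.

``REFERENCE_COMPARTMENT_MEANS`` holds published compartment mean
concentrations (μM) for ten representative metabolites at diagnosis (day 0)
and at the end of induction therapy (day 29); these printed means are the
inputs for the worked mean-difference examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

LIPID = "lipid_metabolism"
AMINO = "amino_acid"
OTHER = "other"
CLASSES = (LIPID, AMINO, OTHER)


@dataclass(frozen=True)
class PanelEntry:
    """One metabolite of a synthetic panel.

    Parameters
    ----------
    name:
        Metabolite name (lower case, whitespace-normalized).
    klass:
        One of ``lipid_metabolism`` / ``amino_acid`` / ``other``.
    mean:
        PB-scale mean concentration in μM; must be positive.
    cv:
        Coefficient of variation of the between-patient log-normal spread.
    shifts:
        Mapping day -> BM-minus-PB mean shift in μM at that day.
    """

    name: str
    klass: str
    mean: float
    cv: float = 0.3
    shifts: dict = field(default_factory=dict)

    def shift(self, day: int) -> float:
        return float(self.shifts.get(day, 0.0))


# name, class, plasma-scale mean (μM)
_DEFAULT_ROWS = [
    # lipid metabolism
    ("choline", LIPID, 30.0),
    ("glycerophosphocholine", LIPID, 20.0),
    ("acetylcarnitine", LIPID, 10.0),
    ("carnitine", LIPID, 40.0),
    ("myristic acid", LIPID, 60.0),
    ("palmitic acid", LIPID, 150.0),
    ("palmitoleic acid", LIPID, 30.0),
    ("oleic acid", LIPID, 120.0),
    ("stearic acid", LIPID, 70.0),
    ("linoleic acid", LIPID, 100.0),
    # amino acids, derivatives, analogues
    ("alanine", AMINO, 350.0),
    ("glutamate", AMINO, 160.0),
    ("glutamine", AMINO, 440.0),
    ("asparagine", AMINO, 50.0),
    ("aspartate", AMINO, 30.0),
    ("glycine", AMINO, 350.0),
    ("valine", AMINO, 220.0),
    ("isoleucine", AMINO, 60.0),
    ("methionine", AMINO, 25.0),
    ("threonine", AMINO, 130.0),
    # other
    ("lactate", OTHER, 2400.0),
    ("glucose", OTHER, 6000.0),
    ("urea", OTHER, 4500.0),
    ("3-hydroxybutyrate", OTHER, 150.0),
    ("acetoacetate", OTHER, 60.0),
    ("acetone", OTHER, 30.0),
    ("pyruvate", OTHER, 70.0),
    ("fumarate", OTHER, 5.0),
    ("hypoxanthine", OTHER, 10.0),
    ("uridine", OTHER, 5.0),
]


def default_panel(cv: float = 0.3) -> list[PanelEntry]:
    """The 30-metabolite synthetic panel with no compartment shifts."""
    return [PanelEntry(n, k, m, cv) for n, k, m in _DEFAULT_ROWS]


def recovery_panel(cv: float = 0.3, shift_fraction: float = 0.3) -> list[PanelEntry]:
    """Panel used by the parameter-recovery study.

    Lipid-class metabolites carry a positive BM-minus-PB mean shift at day 0
    (the cancer state), amino-acid metabolites at day 29 (remission); the
    shift magnitude is ``shift_fraction`` of the metabolite mean, the scale on
    which the correlated difference blocks are planted.
    """
    out = []
    for n, k, m in _DEFAULT_ROWS:
        shifts = {}
        if k == LIPID:
            shifts[0] = shift_fraction * m
        elif k == AMINO:
            shifts[29] = shift_fraction * m
        out.append(PanelEntry(n, k, m, cv, shifts))
    return out


def panel_annotation(panel: list[PanelEntry]) -> dict:
    return {e.name: e.klass for e in panel}


# Published compartment mean concentrations (μM), days 0 and 29, for ten
# representative metabolites of the pediatric ALL study. Columns: B0, P0,
# B0-P0, B29, P29, B29-P29 (printed values; differences as printed, which for
# a few rows differ from the subtraction of the printed means at the 0.01 μM
# level because the study rounded per-patient means).
REFERENCE_COMPARTMENT_MEANS = pd.DataFrame(
    [
        ("lactate", 3418.6, 2378.42, 1040.27, 3648.98, 4067.95, -418.96),
        ("urea", 5018.23, 4464.38, 553.85, 8532.33, 9175.15, -642.82),
        ("glutamate", 459.979, 156.271, 303.71, 205.69, 231.334, -25.64),
        ("triacylglyceride", 2299.07, 2051.74, 247.33, 1488.55, 1527.89, -39.34),
        ("glycine", 450.072, 354.293, 95.78, 405.158, 388.339, 16.82),
        ("glucose", 5375.17, 6066.73, -691.57, 3764.65, 4392.07, -627.42),
        ("cholesterol esters", 3352.81, 3545.79, -192.99, 4085.96, 4050.43, 35.54),
        ("glutamine", 352.78, 442.421, -89.64, 380.068, 372.481, 7.59),
        ("3-hydroxybutyrate", 147.16, 236.31, -89.15, 41.72, 62.46, -20.74),
    ],
    columns=["metabolite", "B0", "P0", "B0_minus_P0", "B29", "P29", "B29_minus_P29"],
).set_index("metabolite")
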