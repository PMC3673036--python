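"""Published characterization values for the four EphB kinase domains.

These constants parameterize the synthetic-data presets: melting
temperatures and van't Hoff enthalpies from CD thermal unfolding,
steady-state kinetic constants from the luminescence phosphorylation
assay, and IC50s for the seven-inhibitor panel.  Errors quoted in the
source tables are reproduced for reference but are not used by the
generator.

Molar masses are *effective* values back-derived from each printed
(kcat, Vmax) pair via M = kcat·6×10⁷/Vmax.  The constructs are all
~298 residues (kinase domain plus an N-terminal GSS cloning remnant),
i.e. ≈ 33.5 kDa by length; the EphB1, EphB3 and EphB3-C717G effective
masses agree with that estimate to ~1%, while the EphB2 and EphB4 rows
imply 37.0 and 39.3 kDa — an internal inconsistency of the published
kinetic table that is documented in docs/methods.md.  Using the
effective masses keeps the kcat↔Vmax conversion exact per enzyme.
"""

from __future__ import annotations

from .data import EnzymeSpec

__all__ = [
    "THERMAL_TABLE",
    "KINETICS_TABLE",
    "IC50_TABLE",
    "ENZYMES",
    "AKAIKE_TABLE",
]

#: CD thermal unfolding: enzyme → (Tm °C, Tm SE, ΔHm kJ/mol, ΔHm SE)
THERMAL_TABLE = {
    "EphB1": (59.7, 0.2, 156.6, 14.3),
    "EphB2": (53.9, 0.2, 154.2, 16.5),
    "EphB3": (45.0, 0.1, 106.2, 3.7),
    "EphB4": (42.8, 0.2, 129.3, 10.7),
}

#: published Akaike probabilities (%, two-state / three-state) for the
#: GdnHCl titrations; "<0.01"/" >99.99" entries stored as 0.01 / 99.99
AKAIKE_TABLE = {
    "EphB1": (1.22, 98.78),
    "EphB2": (0.01, 99.99),
    "EphB3": (0.01, 99.99),
    "EphB4": (0.01, 99.99),
}

#: steady-state kinetics: enzyme → dict of printed values
#: Km in μM (ATP) and μg/ml (poly-(Glu:Tyr)); kcat s⁻¹; Vmax nmol/min/mg
KINETICS_TABLE = {
    "EphB1": {"km_atp": 555.0, "km_atp_se": 36.0,
              "km_polygt": 1137.0, "km_polygt_se": 125.0,
              "kcat": 0.80, "kcat_se": 0.02, "vmax": 1415.0, "vmax_se": 30.0},
    "EphB2": {"km_atp": 751.0, "km_atp_se": 80.0,
              "km_polygt": 1601.0, "km_polygt_se": 190.0,
              "kcat": 1.11, "kcat_se": 0.04, "vmax": 1802.0, "vmax_se": 67.0},
    "EphB3": {"km_atp": 506.0, "km_atp_se": 48.0,
              "km_polygt": 943.0, "km_polygt_se": 91.0,
              "kcat": 0.43, "kcat_se": 0.01, "vmax": 764.0, "vmax_se": 23.0},
    "EphB4": {"km_atp": 497.0, "km_atp_se": 39.0,
              "km_polygt": 1001.0, "km_polygt_se": 122.0,
              "kcat": 0.51, "kcat_se": 0.01, "vmax": 779.0, "vmax_se": 21.0},
    "EphB3-C717G": {"km_atp": 659.0, "km_atp_se": 67.0,
                    "km_polygt": 1458.0, "km_polygt_se": 177.0,
                    "kcat": 0.86, "kcat_se": 0.03, "vmax": 1533.0, "vmax_se": 46.0},
}


def _effective_mass(kcat: float, vmax: float) -> float:
    return round(kcat * 6e7 / vmax)


#: enzyme specs with effective molar masses (see module docstring)
ENZYMES = {
    name: EnzymeSpec(name=name,
                     molar_mass=_effective_mass(row["kcat"], row["vmax"]))
    for name, row in KINETICS_TABLE.items()
}

#: IC50 panel (μM) and fit R²: compound → enzyme → (ic50, r2).
#: Out-of-window entries are the string bound as printed (">100").
IC50_TABLE = {
    "CMPD1": {"EphB1": (0.091, 0.994), "EphB2": (0.088, 0.978),
              "EphB3": (4.958, 0.98), "EphB3-C717G": (0.09, 0.983),
              "EphB4": (0.062, 0.99)},
    "CMPD2": {"EphB1": (0.021, 0.998), "EphB2": (0.016, 0.992),
              "EphB3": (0.149, 0.991), "EphB3-C717G": (0.017, 0.999),
              "EphB4": (0.015, 0.994)},
    "CMPD3": {"EphB1": (0.023, 0.992), "EphB2": (0.021, 0.988),
              "EphB3": (0.036, 0.997), "EphB3-C717G": (0.018, 0.991),
              "EphB4": (0.017, 0.997)},
    "Afatinib": {"EphB1": (5.443, 0.971), "EphB2": (2.488, 0.954),
                 "EphB3": (">100", 0.821), "EphB3-C717G": (3.426, 0.991),
                 "EphB4": (3.165, 0.985)},
    "Dasatinib": {"EphB1": (0.01, 0.999), "EphB2": (0.007, 0.993),
                  "EphB3": (0.007, 0.993), "EphB3-C717G": (0.008, 0.995),
                  "EphB4": (0.006, 0.981)},
    "Sorafenib": {"EphB1": (1.211, 0.986), "EphB2": (0.996, 0.987),
                  "EphB3": (3.584, 0.991), "EphB3-C717G": (0.879, 0.993),
                  "EphB4": (0.495, 0.992)},
    "Sunitinib": {"EphB1": (5.025, 0.992), "EphB2": (2.903, 0.954),
                  "EphB3": (37.27, 0.98), "EphB3-C717G": (2.808, 0.988),
                  "EphB4": (3.47, 0.993)},
}
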