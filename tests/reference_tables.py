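"""Published reference characterization of the 22 released bioactive
di/tripeptides, frozen as validation fixtures.

``RESISTANCE`` holds the digestion products under oligopeptidase F and
proteinase P1.  ``PHYSCHEM`` holds the seven descriptors as printed in the
reference characterization; the GK row's charge, pI and instability cells
are internally inconsistent there (the same method that yields the PK/SK
rows gives +1, 9.70 and −37.45) and are marked for exclusion.
"""

# fragment -> (oligopeptidase F products, proteinase P1 products)
RESISTANCE = {
    "AR": (("AR",), ("AR",)),
    "PGL": (("PGL",), ("P", "G", "L")),
    "CF": (("CF",), ("CF",)),
    "EK": (("EK",), ("EK",)),
    "TF": (("TF",), ("TF",)),
    "IL": (("IL",), ("I", "L")),
    "GL": (("GL",), ("G", "L")),
    "IY": (("IY",), ("IY",)),
    "ER": (("ER",), ("ER",)),
    "VF": (("VF",), ("V", "F")),
    "AW": (("AW",), ("AW",)),
    "PL": (("PL",), ("P", "L")),
    "GF": (("GF",), ("GF",)),
    "GK": (("GK",), ("GK",)),
    "PK": (("PK",), ("P", "K")),
    "TW": (("TW",), ("TW",)),
    "PW": (("PW",), ("P", "W")),
    "SK": (("SK",), ("SK",)),
    "PF": (("PF",), ("P", "F")),
    "IM": (("IM",), ("IM",)),
    "QH": (("QH",), ("Q", "H")),
    "QL": (("QL",), ("Q", "L")),
}

RESISTANT_BOTH = {
    "AR", "CF", "EK", "TF", "IY", "ER", "AW", "GF", "GK", "TW", "SK", "IM",
}

# fragment -> (boman kcal/mol, net charge at pH 7, pI, instability,
#              aliphatic, gravy, solubility)
PHYSCHEM = {
    "AR": (6.55, 1.0, 10.55, 5.0, 50.0, -1.35, "good"),
    "PGL": (-1.95, 0.0, 6.10, 6.67, 130.00, 0.60, "poor"),
    "CF": (-2.13, -0.1, 5.92, 5.0, 0.0, 2.65, "poor"),
    "EK": (6.18, 0.0, 6.41, 5.0, 0.0, -3.70, "good"),
    "TF": (-0.2, 0.0, 6.10, 66.70, 0.0, 1.05, "poor"),
    "IL": (-4.92, 0.0, 6.10, 101.30, 390.00, 4.15, "poor"),
    "GL": (-2.93, 0.0, 6.10, 5.0, 195.00, 1.70, "poor"),
    "IY": (-2.39, 0.0, 6.09, 5.0, 195.00, 1.60, "poor"),
    "ER": (10.86, 0.0, 6.41, 5.0, 0.0, -4.00, "good"),
    "VF": (-3.51, 0.0, 6.10, 5.0, 145.00, 3.50, "poor"),
    "AW": (-2.07, 0.0, 6.10, 5.0, 50.0, 0.45, "poor"),
    "PL": (-2.46, 0.0, 6.10, 5.0, 195.00, 1.10, "poor"),
    "GF": (-1.96, 0.0, 6.10, 5.0, 0.0, 1.20, "poor"),
    "GK": (2.30, 0.0, 6.70, -3745.0, 0.0, -2.15, "good"),
    "PK": (2.77, 1.0, 9.70, 5.0, 0.0, -2.75, "good"),
    "TW": (0.11, 0.0, 6.10, -70.15, 0.0, -0.80, "poor"),
    "PW": (-1.16, 0.0, 6.10, -9.40, 0.0, -1.25, "poor"),
    "SK": (4.47, 1.0, 9.70, 5.0, 0.0, -2.35, "good"),
    "PF": (-1.49, 0.0, 6.10, 101.30, 0.0, 0.60, "poor"),
    "IM": (-3.63, 0.0, 6.10, 5.0, 195.00, 3.20, "poor"),
    "QH": (5.09, 0.1, 7.55, 5.0, 0.0, -3.35, "good"),
    "QL": (0.31, 0.0, 6.10, 5.0, 195.00, 0.15, "poor"),
}

#: Fragments whose printed charge/pI/instability cells are inconsistent
#: with the method that produced every other row.
PHYSCHEM_ANOMALOUS = {"GK"}

GOOD_SOLUBILITY = {"AR", "EK", "ER", "GK", "PK", "SK", "QH"}
HIGH_BINDING = {"AR", "EK", "ER", "PK", "SK", "QH"}
UNSTABLE = {"TF", "IL", "PF"}
THERMOSTABLE = {"PGL", "IL", "GL", "IY", "VF", "PL", "IM", "QL"}

#: Source accession cited in the activity snapshot but absent from the
#: printed 57-record panel; releases from it can never be reproduced.
SOURCES_NOT_IN_PANEL = {"AP01328"}
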