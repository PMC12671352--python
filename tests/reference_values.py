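"""Published reference values used as test oracles.

Values are stored as the strings printed in the survey's report tables,
so each comparison can honour the precision at which a cell was printed
(several columns mix one, two and three printed decimals, and the
published tables were assembled from rounded intermediates).
"""

HI_ORDER = ("Mn", "Fe", "Cu", "Zn", "As", "Cd", "Pb")

# Published per-sample risk-index table: sample -> (EDI strings in
# HI_ORDER, THQ strings in HI_ORDER, HI string).
PRINTED_RISK_TABLE = {
    "CS1A": (("177.1", "537.14", "88.36", "874.1", "0.1", "2.3", "6.89"),
             ("1.26", "0.77", "2.209", "2.914", "0.33", "2.3", "1.72"),
             "11.53"),
    "CS1M": (("320.78", "499.69", "58.74", "77.11", "0.08", "0.7", "11.7"),
             ("2.29", "0.71", "1.469", "0.257", "0.25", "0.7", "2.93"),
             "8.64"),
    "CS2A": (("1193.9", "277.56", "80.42", "540.9", "0.06", "1.3", "4.11"),
             ("8.53", "0.4", "2.011", "1.803", "0.19", "1.3", "1.03"),
             "15.28"),
    "CS2M": (("238.82", "624.26", "71.21", "76.74", "0.12", "0.3", "11.9"),
             ("1.71", "0.89", "1.78", "0.256", "0.41", "0.3", "2.98"),
             "8.28"),
    "CS2P": (("201.32", "546.2", "119.4", "842.9", "0.07", "3", "7.54"),
             ("1.44", "0.78", "2.984", "2.81", "0.24", "3", "1.88"),
             "13.18"),
    "CS3A": (("134.07", "592.44", "33.15", "637", "0.08", "2.2", "6.05"),
             ("0.96", "0.85", "0.829", "2.123", "0.28", "2.2", "1.51"),
             "8.77"),
    "CS3M": (("71.11", "450.43", "28.24", "84.14", "0.06", "0.4", "6.14"),
             ("0.51", "0.64", "0.706", "0.28", "0.21", "0.4", "1.53"),
             "4.28"),
    "CS3P": (("129.13", "1565.3", "24.19", "299", "0.27", "0.8", "32"),
             ("0.92", "2.24", "0.605", "0.997", "0.9", "0.8", "8"),
             "14.47"),
    "CS4A": (("67.59", "615.5", "23.29", "266.8", "0.07", "0.8", "4.45"),
             ("0.48", "0.88", "0.582", "0.889", "0.23", "0.8", "1.11"),
             "4.96"),
    "CS4M": (("130.74", "282.58", "24.41", "51.58", "0.04", "0.1", "2.48"),
             ("0.93", "0.4", "0.61", "0.172", "0.13", "0.1", "0.62"),
             "2.98"),
    "CS4P": (("390.7", "1991.19", "97.16", "100.3", "0.32", "0.3", "25.5"),
             ("2.79", "2.84", "2.429", "0.334", "1.06", "0.3", "6.39"),
             "16.11"),
    "LS1A": (("350.08", "1847.4", "5.53", "262.9", "0.25", "0.2", "2.88"),
             ("2.5", "2.64", "0.138", "0.876", "0.84", "0.2", "0.72"),
             "7.94"),
    "LS1M": (("303.83", "1105.2", "7.81", "61.97", "0.17", "0.1", "1.95"),
             ("2.17", "1.58", "0.195", "0.207", "0.57", "0.1", "0.49"),
             "5.33"),
    "LS2A": (("299.61", "767.07", "8.144", "158.6", "0.13", "0.1", "1.26"),
             ("2.14", "1.1", "0.204", "0.529", "0.42", "0.1", "0.31"),
             "4.85"),
    "LS2M": (("341.35", "842.21", "7.115", "86.91", "0.11", "0.2", "1.47"),
             ("2.44", "1.2", "0.178", "0.29", "0.38", "0.2", "0.37"),
             "5.04"),
    "LS3A": (("504.92", "2790", "10.39", "182.7", "0.4", "0.5", "4.04"),
             ("3.61", "3.99", "0.26", "0.609", "1.34", "0.5", "1.01"),
             "11.29"),
    "LS3M": (("244.92", "1480.8", "34.75", "65.17", "0.22", "0.1", "3.34"),
             ("1.75", "2.12", "0.869", "0.217", "0.72", "0.1", "0.84"),
             "6.6"),
    "LS4A": (("1001.4", "1278.4", "7.915", "287", "0.22", "0.6", "2.82"),
             ("7.15", "1.83", "0.198", "0.957", "0.72", "0.6", "0.71"),
             "12.15"),
    "LS4M": (("374.16", "1193.1", "7.898", "32.87", "0.19", "0.2", "2.49"),
             ("2.67", "1.7", "0.197", "0.11", "0.62", "0.2", "0.62"),
             "6.11"),
}

# Published per-site HI extrema.
HI_EXTREMA = {"Cecomaf": ("2.98", "16.11"), "Lutendele": ("4.85", "12.15")}

# Published per-site maxima quoted in the survey's results narrative
# (each value is the maximum within the named site).
SITE_MAXIMA = {
    "Lutendele": {"Ti": 39.77, "V": 4.38, "Mn": 968.05, "Fe": 2696.99,
                  "Co": 0.89, "As": 0.39, "Se": 0.58, "Mo": 3.55},
    "Cecomaf": {"Cr": 4.55, "Ni": 6.18, "Cu": 115.39, "Zn": 844.94,
                "Ag": 0.04, "Cd": 2.95, "Sn": 1.93, "Sb": 0.26,
                "Ba": 137.91, "Pb": 30.94, "Hg": 0.058},
}

# Published rank-correlation coefficients (three decimals).
PRINTED_SPEARMAN = {
    ("Cecomaf", "Cr", "As"): 0.855,
    ("Cecomaf", "Cr", "Pb"): 0.929,
    ("Cecomaf", "Cd", "Hg"): 0.564,
    ("Lutendele", "Cr", "As"): 0.910,
    ("Lutendele", "Cr", "Pb"): 0.881,
    ("Lutendele", "Cd", "Hg"): 0.524,
}

# Published fold exceedances of the food limits that are arithmetically
# consistent with the concentration table (the published Pb fold, 103.3,
# disagrees with its own table, which gives 30.94/0.3 = 103.1, and is
# deliberately not asserted).
PRINTED_FOLDS = {"Cr": 3.5, "Cd": 29.5, "Hg": 58.0}


def printed_tolerance(text: str) -> float:
    """Comparison tolerance for one printed cell: 0.02 absolute or 1 %
    relative, whichever is larger, floored at half an ulp of the
    precision the cell was printed at (cells printed at one or zero
    decimals carry +-0.05 / +-0.5 rounding radius by construction)."""
    decimals = len(text.split(".")[1]) if "." in text else 0
    return max(0.02, 0.01 * abs(float(text)), 0.5 * 10.0 ** (-decimals))
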