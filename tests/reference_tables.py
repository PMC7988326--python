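"""Published raw/adjusted p-value columns used as fixed reference inputs.

Raw p-values are inputs to the multiple-testing layer; the printed adjusted
values are exact functions of them under BH with the family sizes implied by
the tables themselves (ratio of adjusted to raw at rank 1). All values as
printed, 4 significant figures.
"""

# Pan-cancer single-gene analysis: (gene, n_carriers, effect, p_raw, p_adjusted),
# family size 67.
TABLE1 = [
    ("APC", 53, 2.51, 7.910e-09, 5.300e-07),
    ("FANCL", 82, 3.77, 9.500e-08, 3.180e-06),
    ("SLC25A13", 17, 11.46, 1.938e-04, 4.329e-03),
    ("TP53", 16, 8.87, 4.897e-03, 8.202e-02),
    ("ERCC3", 23, 6.87, 9.044e-03, 1.212e-01),
    ("MSH6", 20, 6.34, 2.453e-02, 2.348e-01),
    ("PMS2", 32, 5.05, 2.367e-02, 2.348e-01),
]
TABLE1_FAMILY = 67

# Per-cancer gene-set analysis: cancer -> (family size, [(p_raw, p_adjusted)]).
# The three SKCM rows printing adjusted 3.568E-02 are omitted: that value is
# not a function of the printed raw p-values under BH with m=20 (the step-down
# minimum was evidently driven by a family member absent from the table).
TABLE2 = {
    "UCEC": (23, [
        (8.712e-31, 2.004e-29), (7.358e-30, 8.462e-29), (4.704e-23, 3.607e-22),
        (1.132e-22, 6.508e-22), (5.317e-21, 2.446e-20), (1.828e-20, 7.009e-20),
        (3.925e-13, 1.290e-12), (9.928e-10, 2.854e-09), (1.396e-09, 3.568e-09),
        (1.040e-08, 2.393e-08), (2.932e-08, 6.130e-08), (1.958e-06, 3.753e-06),
        (3.065e-06, 5.423e-06), (9.955e-06, 1.635e-05), (4.291e-04, 6.580e-04),
        (4.835e-04, 6.950e-04),
    ]),
    "SKCM": (20, [
        (6.214e-04, 1.243e-02), (1.680e-03, 1.680e-02), (2.805e-03, 1.870e-02),
        (6.340e-03, 2.851e-02), (7.643e-03, 2.851e-02), (8.553e-03, 2.851e-02),
        (1.027e-02, 2.903e-02), (1.161e-02, 2.903e-02),
    ]),
    "COAD": (18, [
        (4.064e-06, 7.315e-05), (2.467e-03, 2.220e-02),
    ]),
}
# raw p-values of the three SKCM rows excluded above; needed to complete the
# supplied subset when adjusting the SKCM family (their own adjusted values
# are not asserted)
TABLE2_SKCM_TAIL_RAW = [1.696e-02, 1.827e-02, 2.029e-02]

# Pan-cancer gene-set analysis, family size 208; the tied top pair (two merged
# units with identical carriers) both print the rank-2 value.
TABLE3 = [
    (7.907e-09, 8.223e-07), (7.907e-09, 8.223e-07), (3.466e-07, 2.403e-05),
    (2.517e-06, 1.309e-04), (3.729e-06, 1.551e-04), (2.086e-05, 7.231e-04),
    (1.299e-04, 3.378e-03), (1.241e-04, 3.378e-03), (1.938e-04, 4.480e-03),
    (2.993e-04, 6.226e-03), (4.116e-04, 7.782e-03), (4.615e-04, 7.999e-03),
]
TABLE3_FAMILY = 208
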