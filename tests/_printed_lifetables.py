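"""Published life-table point estimates used as arithmetic-identity inputs.

One row per (sex, diabetes group, cohort, domain, baseline age):
(disability-free years, disabled years, life-years lost, onset age),
as printed to one decimal in the source report's summary tables.
"""

PRINTED_ROWS = {
    # men, diabetes
    ("male", "diabetes", 1, "mobility", 50): (13.0, 4.2, 2.8, 63.0),
    ("male", "diabetes", 2, "mobility", 50): (14.8, 3.6, 1.5, 64.8),
    ("male", "diabetes", 1, "mobility", 60): (6.8, 1.6, 1.6, 66.8),
    ("male", "diabetes", 2, "mobility", 60): (7.9, 0.9, 1.3, 67.9),
    ("male", "diabetes", 1, "iadl", 50): (13.5, 3.7, 2.8, 63.5),
    ("male", "diabetes", 2, "iadl", 50): (14.3, 4.1, 1.5, 64.3),
    ("male", "diabetes", 1, "iadl", 60): (6.9, 1.6, 1.6, 66.9),
    ("male", "diabetes", 2, "iadl", 60): (7.8, 0.9, 1.3, 67.8),
    ("male", "diabetes", 1, "adl", 50): (12.7, 4.5, 2.8, 62.7),
    ("male", "diabetes", 2, "adl", 50): (15.0, 3.5, 1.5, 65.0),
    ("male", "diabetes", 1, "adl", 60): (6.4, 2.0, 1.6, 66.4),
    ("male", "diabetes", 2, "adl", 60): (7.8, 0.9, 1.3, 67.8),
    # men, no diabetes
    ("male", "no_diabetes", 1, "mobility", 50): (17.0, 1.8, 1.2, 67.0),
    ("male", "no_diabetes", 2, "mobility", 50): (17.9, 1.5, 0.6, 67.9),
    ("male", "no_diabetes", 1, "mobility", 60): (8.6, 0.7, 0.7, 68.6),
    ("male", "no_diabetes", 2, "mobility", 60): (9.1, 0.4, 0.5, 69.1),
    ("male", "no_diabetes", 1, "iadl", 50): (16.9, 1.9, 1.2, 66.9),
    ("male", "no_diabetes", 2, "iadl", 50): (17.4, 2.0, 0.6, 67.4),
    ("male", "no_diabetes", 1, "iadl", 60): (8.5, 0.8, 0.7, 68.5),
    ("male", "no_diabetes", 2, "iadl", 60): (9.1, 0.4, 0.5, 69.1),
    ("male", "no_diabetes", 1, "adl", 50): (16.4, 2.4, 1.2, 66.4),
    ("male", "no_diabetes", 2, "adl", 50): (17.6, 1.8, 0.6, 67.6),
    ("male", "no_diabetes", 1, "adl", 60): (8.3, 1.0, 0.7, 68.3),
    ("male", "no_diabetes", 2, "adl", 60): (9.0, 0.5, 0.5, 69.0),
    # women, diabetes
    ("female", "diabetes", 1, "mobility", 50): (11.3, 6.8, 1.9, 61.3),
    ("female", "diabetes", 2, "mobility", 50): (13.2, 5.7, 1.1, 63.2),
    ("female", "diabetes", 1, "mobility", 60): (6.2, 2.7, 1.1, 66.2),
    ("female", "diabetes", 2, "mobility", 60): (7.6, 1.4, 0.9, 67.6),
    ("female", "diabetes", 1, "iadl", 50): (13.0, 5.1, 1.9, 63.0),
    ("female", "diabetes", 2, "iadl", 50): (14.1, 4.8, 1.1, 64.1),
    ("female", "diabetes", 1, "iadl", 60): (6.8, 2.2, 1.1, 66.8),
    ("female", "diabetes", 2, "iadl", 60): (8.0, 1.1, 0.9, 68.0),
    ("female", "diabetes", 1, "adl", 50): (12.3, 5.8, 1.9, 62.3),
    ("female", "diabetes", 2, "adl", 50): (14.6, 4.3, 1.1, 64.6),
    ("female", "diabetes", 1, "adl", 60): (6.3, 2.6, 1.1, 66.3),
    ("female", "diabetes", 2, "adl", 60): (7.9, 1.2, 0.9, 67.9),
    # women, no diabetes
    ("female", "no_diabetes", 1, "mobility", 50): (16.1, 3.1, 0.8, 66.1),
    ("female", "no_diabetes", 2, "mobility", 50): (17.2, 2.4, 0.4, 67.2),
    ("female", "no_diabetes", 1, "mobility", 60): (8.4, 1.2, 0.4, 68.4),
    ("female", "no_diabetes", 2, "mobility", 60): (9.1, 0.6, 0.4, 69.1),
    ("female", "no_diabetes", 1, "iadl", 50): (16.6, 2.6, 0.8, 66.6),
    ("female", "no_diabetes", 2, "iadl", 50): (17.2, 2.3, 0.4, 67.2),
    ("female", "no_diabetes", 1, "iadl", 60): (8.5, 1.1, 0.4, 68.5),
    ("female", "no_diabetes", 2, "iadl", 60): (9.1, 0.5, 0.4, 69.1),
    ("female", "no_diabetes", 1, "adl", 50): (16.2, 3.1, 0.8, 66.2),
    ("female", "no_diabetes", 2, "adl", 50): (17.4, 2.2, 0.4, 67.4),
    ("female", "no_diabetes", 1, "adl", 60): (8.2, 1.3, 0.4, 68.2),
    ("female", "no_diabetes", 2, "adl", 60): (9.1, 0.6, 0.4, 69.1),
}

#: published annual rate per 100 PY: (onset, recovery, death_nd, death_dis)
#: diabetic adults, pooled ages, mobility domain
OPERATING_POINT = (0.067, 0.159, 0.029, 0.045)

#: published obesity prevalence (percent) among diabetic adults at the two
#: baselines: class II 10.7 -> 18.5, class III 6.4 -> 14.3
OBESITY_PREVALENCE = {"class_2": (10.7, 18.5), "class_3": (6.4, 14.3)}
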