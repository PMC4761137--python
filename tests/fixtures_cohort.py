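"""Published-style cohort margins used as inputs to summary-arithmetic checks.

Counts of analyzed urinary-tract cancer cases by site and sex for the recent
(1998-2010) provincial era: totals, in-situ counts, geocode-precision shares
(civic-address exact / postal-code region-set / town-name coarse) and mean
age at diagnosis.
"""

NS_RECENT_MARGINS = {
    ("bladder", "F"): dict(total=820, in_situ=298,
                           precision=(0.855, 0.0207, 0.124), mean_age=71.2),
    ("bladder", "M"): dict(total=2412, in_situ=866,
                           precision=(0.869, 0.0236, 0.107), mean_age=70.5),
    ("kidney", "F"): dict(total=848, in_situ=0,
                          precision=(0.864, 0.0165, 0.119), mean_age=66.0),
    ("kidney", "M"): dict(total=1295, in_situ=0,
                          precision=(0.855, 0.0239, 0.121), mean_age=63.7),
}


def build_recent_cohort():
    from riskmap.synthetic import cases_from_margins

    cases = []
    for (site, sex), m in NS_RECENT_MARGINS.items():
        cases.extend(cases_from_margins(site, sex, (1998, 2010), m["total"],
                                        m["in_situ"], m["precision"],
                                        m["mean_age"]))
    return cases
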