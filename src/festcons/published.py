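"""Published summary counts from a genome-wide survey of alternative
splicing in nine flowering plants.

These are the raw event/gene/cluster tallies of that survey, shipped as
validation inputs: the reporting module's percentage arithmetic must
reproduce the survey's printed percentages from these counts.  They are
*data*, not results of this package.
"""

from __future__ import annotations

SPECIES = (
    "Amborella", "Arabidopsis", "Soybean", "Medicago", "Rice",
    "Common bean", "Poplar", "Tomato", "Grape",
)

# per event type: events detected per species (survey-wide totals)
EVENT_COUNTS: dict[str, dict[str, int]] = {
    "AltA": {
        "Amborella": 9427, "Arabidopsis": 5377, "Soybean": 13056,
        "Medicago": 6115, "Rice": 6110, "Common bean": 5675,
        "Poplar": 7807, "Tomato": 3918, "Grape": 7373,
    },
    "AltD": {
        "Amborella": 7166, "Arabidopsis": 3168, "Soybean": 9055,
        "Medicago": 4237, "Rice": 3514, "Common bean": 3575,
        "Poplar": 4541, "Tomato": 2127, "Grape": 5315,
    },
    "ExonS": {
        "Amborella": 6119, "Arabidopsis": 1186, "Soybean": 5647,
        "Medicago": 2409, "Rice": 2493, "Common bean": 2316,
        "Poplar": 2491, "Tomato": 1734, "Grape": 3850,
    },
    "IntronR": {
        "Amborella": 28328, "Arabidopsis": 18325, "Soybean": 28262,
        "Medicago": 14710, "Rice": 16100, "Common bean": 10440,
        "Poplar": 23190, "Tomato": 8655, "Grape": 29184,
    },
}

# printed total events per species (the survey's own totals row)
TOTAL_EVENTS: dict[str, int] = {
    "Amborella": 51041, "Arabidopsis": 28057, "Soybean": 56021,
    "Medicago": 27472, "Rice": 28218, "Common bean": 22007,
    "Poplar": 38030, "Tomato": 16435, "Grape": 45723,
}

# printed per-species percentages for intron retention (for the
# unweighted-mean headline figure)
PRINTED_INTRONR_PCT: dict[str, float] = {
    "Amborella": 55.5, "Arabidopsis": 65.3, "Soybean": 50.4,
    "Medicago": 53.6, "Rice": 57.1, "Common bean": 47.4,
    "Poplar": 61.0, "Tomato": 52.7, "Grape": 63.8,
}

# conserved clusters between the two legumes (one diploid-like species,
# one recent-WGD species): conserved events and totals per species
LEGUME_PAIR = {
    "conserved_events": {"Common bean": 7214, "Soybean": 10062},
    "total_events": {"Common bean": 22006, "Soybean": 56020},
    "conserved_genes": {"Common bean": 4020, "Soybean": 5671},
    "total_genes": {"Common bean": 8931, "Soybean": 18475},
}

# conserved clusters across the nine species, stratified by how many
# distinct species each cluster spans
CONSERVED_STRATA: dict[int, dict[str, int]] = {
    2: {"AltA": 3691, "AltD": 1945, "ExonS": 808, "IntronR": 9972},
    3: {"AltA": 1053, "AltD": 435, "ExonS": 142, "IntronR": 4246},
    4: {"AltA": 362, "AltD": 141, "ExonS": 36, "IntronR": 1855},
    5: {"AltA": 217, "AltD": 70, "ExonS": 22, "IntronR": 859},
    6: {"AltA": 116, "AltD": 57, "ExonS": 13, "IntronR": 413},
    7: {"AltA": 64, "AltD": 34, "ExonS": 13, "IntronR": 254},
    8: {"AltA": 39, "AltD": 24, "ExonS": 10, "IntronR": 128},
    9: {"AltA": 20, "AltD": 8, "ExonS": 5, "IntronR": 68},
}


def strata_totals() -> dict[int, int]:
    return {n: sum(row.values()) for n, row in CONSERVED_STRATA.items()}


def type_totals() -> dict[str, int]:
    out: dict[str, int] = {}
    for row in CONSERVED_STRATA.values():
        for etype, n in row.items():
            out[etype] = out.get(etype, 0) + n
    return out


def grand_total() -> int:
    return sum(strata_totals().values())
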