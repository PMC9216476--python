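"""Categorical call values of the supported pathogenicity predictors."""

from enum import Enum


class Sift(str, Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    ABSENT = "absent"


class MutationTaster(str, Enum):
    DISEASE_CAUSING = "disease_causing"
    POLYMORPHISM = "polymorphism"
    ABSENT = "absent"


class Polyphen(str, Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    ABSENT = "absent"


class StatReason(str, Enum):
    """Why the statistical knowledge score has its value."""

    ASSIGNED = "assigned"
    PRESENT_IN_POPULATION_PANEL = "present_in_population_panel"
    CLINICAL_RELEVANCE_MISSING = "clinical_relevance_missing"
    INSUFFICIENT_INFORMATION = "insufficient_information"
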