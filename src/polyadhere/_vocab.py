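"""Closed vocabularies: GSASA-derived DRP taxonomy and schema value sets.

The drug-related-problem cause list is the GSASA classification adapted for
community-pharmacy medication reviews: the single "insufficient knowledge"
cause is split into three information-need subdomains (safe and effective
use, adverse drug reactions, lifestyle/nutrition/empowerment) and a
"More cost-effective therapy available" cause is added, since generic
substitution is a typical medication-review recommendation.

Each vocabulary maps a label to the reference tally observed in one
medication-review arm (N = 258 problems over 218 patients); the tallies
drive the synthetic generator's multinomial draws and double as a worked
dataset for the summary arithmetic.
"""

from __future__ import annotations

# cause label -> reference count (sums to 258)
DRP_CAUSES: dict[str, int] = {
    "Insufficient adherence": 69,
    "Patient needs information about safe and effective use of his medicines": 50,
    "Patient needs information about potential medicines' adverse drug reaction": 19,
    "Inappropriate timing or frequency of administration": 18,
    "Under-dosed therapy": 15,
    "Drug-drug/drug-food interaction": 14,
    "Adverse effect": 12,
    "Inappropriate therapy duration": 10,
    "Inappropriate drug administration": 9,
    "Patient needs information about lifestyle, nutrition or empowerment": 8,
    "Not received treatment": 7,
    "More cost-effective therapy available": 5,
    "No concordance with guidelines or contraindication": 4,
    "No dose adjustment because of pathological changes (renal/liver failure)": 4,
    "Not indicated drug or duplication": 3,
    "Incomplete patient documentation": 3,
    "Over-dosed therapy": 3,
    "Prescribed drug not available": 2,
    "Inappropriate monitoring": 1,
    "Not classifiable": 2,
}

# intervention label -> reference count (sums to 258)
DRP_INTERVENTIONS: dict[str, int] = {
    "Counseling of patient, training": 152,
    "Optimisation of administration": 40,
    "Information to other caregivers": 24,
    "Dose adjustment": 12,
    "Substitution of a therapy": 10,
    "Therapy started/restarted": 7,
    "Therapy stopped": 7,
    "Therapy monitoring": 3,
    "Clarification in the patient history": 2,
    "Not classifiable": 1,
}

DRP_STATUS: dict[str, int] = {"potential": 149, "manifest": 109}
DRP_URGENCY: dict[str, int] = {"high": 36, "medium": 113, "low": 109}
DRP_ACCEPTED: dict[str, int] = {"yes": 219, "no": 25, "unclear": 14}

# schema value sets -------------------------------------------------------

FORMS = frozenset({"oral_solid", "oral_other", "topical", "drops", "other"})
ORAL_FORMS = frozenset({"oral_solid", "oral_other"})
REGIMEN_TYPES = frozenset({"daily_fixed", "on_demand"})
REPORTED_CHANGES = frozenset(
    {"dosage_change", "generic_substitution", "start_stop", "no_change"}
)
ARMS = frozenset({"intervention", "control"})
TIMEPOINTS = ("T0", "T2", "T16", "T28")

# ATC class prefixes excluded as chronic on-demand therapies: pain killers
# (N02, M01A), benzodiazepine anxiolytics (N05BA), magnesium (A12CC).
ON_DEMAND_ATC_PREFIXES = ("N02", "M01A", "N05BA", "A12CC")
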