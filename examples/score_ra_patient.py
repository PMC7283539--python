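"""Score one patient with the RA logistic model, step by step.

A screened patient (>= 1 RA diagnosis code) is a case when the logistic
probability over their feature counts reaches the cutoff (default 0.632).
RA diagnoses and positive rheumatoid-factor labs raise the probability;
SLE / psoriatic-arthritis codes and encounter volume lower it."""

from datetime import date

from phenofrag import (
    ClinicalEvent,
    Patient,
    events_to_frame,
    extract_ra_features,
    load_codelists,
    make_view,
    patients_to_frame,
    ra_score,
)
from phenofrag.ra_phenotype import load_ra_model

codelists, model = load_codelists(), load_ra_model()


def e(code_system, code, event_type="diagnosis", value=None, key=""):
    return ClinicalEvent("PT1", event_type, code_system, code, value,
                         date(2014, 5, 1), "Mayo", "billing", key)


events = events_to_frame(
    [
        e("ICD9CM", "714.0", key="K1"),
        e("ICD10CM", "M06.9", key="K2"),
        e("ICD9CM", "714.0", key="K3"),
        e("LAB", "RF", event_type="lab", value=88.0, key="K4"),  # positive (>= 15)
        *[e("NONE", "INPERSON", event_type="encounter", key=f"E{i}") for i in range(8)],
    ]
)
view = make_view(events, patients_to_frame([Patient("PT1")]), ["Mayo"], "Mayo")

features = extract_ra_features(view, "PT1", codelists, model)
probability = ra_score(features, model)
print("feature counts:", features.as_dict())
print(f"probability = {probability:.3f}  (cutoff {model.cutoff})")
print("call:", "case" if probability >= model.cutoff else "screened, not a case")
# Three RA codes plus a positive RF outweigh the encounter penalty.
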