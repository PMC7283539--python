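"""Walk the T2DM case decision tree and the control screen on hand-built
evidence vectors.

The case rule is an ordered disjunction of paths over aggregated evidence
(diagnoses, medication orders, abnormal labs, physician-asserted diagnoses);
the control screen is a conjunction of six requirements."""

from phenofrag import T2DMEvidence, classify_t2dm_case, classify_t2dm_control, load_t2dm_rules

rules = load_t2dm_rules()

examples = {
    "dx + med (typical case)": T2DMEvidence(n_t2dm_dx=2, has_t2dm_med=True),
    "dx + abnormal lab, no med": T2DMEvidence(n_t2dm_dx=1, has_abnormal_lab=True),
    "T1DM dx, both meds, T2DM first": T2DMEvidence(
        n_t1dm_dx=1, n_t2dm_dx=1, has_t1dm_med=True, has_t2dm_med=True,
        t2dm_med_precedes_t1dm_med=True,
    ),
    "isolated dx (insufficient)": T2DMEvidence(n_t2dm_dx=1),
}
for name, evidence in examples.items():
    label, path = classify_t2dm_case(evidence, rules)
    print(f"{name:35s} -> {label}" + (f" via {path}" if path else ""))

print()
clean = T2DMEvidence(n_inperson_visits=2, n_glucose_measures=1)
fam = T2DMEvidence(n_inperson_visits=2, n_glucose_measures=1, family_history_dm=True)
print("2 visits + normal glucose          ->", classify_t2dm_control(clean, rules))
print("same but family history of DM      ->", classify_t2dm_control(fam, rules))
# A single failed screen (here self-reported family history) removes a control.
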