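"""Generate a small synthetic multi-institution cohort and inspect its shape.

The generator draws latent RA / T2DM status at the configured benchmark
prevalences, builds each patient's event stream, and fragments the events
between a home EHR ("Mayo") and a record-linkage source ("REP")."""

from phenofrag import SimulationConfig, generate_cohort

config = SimulationConfig(n_patients=1000, seed=42)
patients, events, truth = generate_cohort(config)

print(f"patients: {len(patients)}, event rows: {len(events)}")
print(f"latent RA cases:        {int(truth['ra_status'].sum())}")
print(f"latent T2DM cases:      {(truth['t2dm_status'] == 'case').sum()}")
print(f"latent T2DM controls:   {(truth['t2dm_status'] == 'control_eligible').sum()}")
print("\nevent rows per source (duplicates counted once per source):")
print(events["source_id"].value_counts().to_string())
print("\nshare of distinct events visible to each source:")
n_events = events["linkage_key"].nunique()
for src in config.sources:
    seen = events.loc[events["source_id"] == src, "linkage_key"].nunique()
    print(f"  {src}: {seen / n_events:.2f}")
# The home EHR misses outside care; the linkage source sees nearly everything.
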