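"""Model selection over frequency intervals and subspace ranks.

Runs the sweep on a reduced grid (150 MHz steps instead of 50 MHz) so it
finishes in seconds; the full-resolution sweep enumerates 465 intervals and
takes minutes.  The lesion contrast here is confined to >= 1.0 GHz, so a
good selection should start near that band.
"""

from mwtriage import SyntheticConfig, generate_cohort, sweep_model_selection

cohort = generate_cohort(
    SyntheticConfig(
        n_patients=14,
        n_controls=14,
        freq_start=0.10,
        freq_stop=1.90,
        freq_step=0.15,
        lesion_band=(1.0, 1.9),
        hematoma_gain=0.06,
        seed=2,
    )
)
sweep = sweep_model_selection(
    cohort, f_start=0.10, f_stop=1.90, step=0.15, min_width=0.45, ranks=[1, 2]
)

print(f"candidate (interval, rank) pairs evaluated: {len(sweep.table)}")
print(f"selected subspace rank: {sweep.selected_rank}")
lo, hi = sweep.selected_interval
print(f"selected frequency interval: {lo:.2f}-{hi:.2f} GHz")
best = sweep.table[
    (sweep.table["f_lo"] == lo)
    & (sweep.table["f_hi"] == hi)
    & (sweep.table["rank"] == sweep.selected_rank)
].iloc[0]
print(f"  AUC {best['auc']:.2f}, specificity at full sensitivity "
      f"{best['spec_at_full_sens']:.2f}")
print()
print("The rank is chosen by the highest AUC averaged over all intervals;")
print("the interval by the highest specificity at 100% sensitivity at that")
print("rank.  The true signal band starts at 1.0 GHz - the selected start")
print("should sit near it.")
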