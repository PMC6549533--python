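"""Activity depression and recovery under 1 Hz low-frequency stimulation.

Simulates 8 wells through a four-set LFS protocol, bins spikes and SBFs
at 15 min (stimulation bins masked), normalizes to the final baseline bin
and compares the post-stimulation bins against baseline with Dunnett's
test — the LTD-like depression readout.
"""

from measync import SimParams, run_lfs_experiment

params = SimParams(sporadic_rate=3.0, intra_burst_rate=25.0)
res = run_lfs_experiment(
    params, n_wells=8, seed=7, baseline_s=3600.0, post_s=14400.0
)

spikes_post = res.spikes_pct.iloc[:, res.post_stim_bins].mean()
sbf_post = res.sbf_pct.iloc[:, res.post_stim_bins].mean()
pv = res.dunnett("spikes").pvalues

print("15-min bins immediately after each stimulation set (% of baseline):")
for k, (b, sp, sb) in enumerate(zip(res.post_stim_bins, spikes_post, sbf_post), 1):
    print(f"  after stim {k}: spikes {sp:6.1f} %   SBFs {sb:6.1f} %   "
          f"Dunnett p(spikes) = {pv.iloc[k - 1]:.2e}")
final = res.spikes_pct.iloc[:, -1].mean()
print(f"spikes ~4 h after the last set: {final:.1f} % (recovered)")
# Spike counts drop ~15-20% right after each set and creep back with the
# slow recovery constant; SBFs recover within ~30 min.
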