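"""MUA V_RMS firing surrogate and up/down-state correlation.

High-passes the 20 kHz extracellular signal above 400 Hz, computes RMS
voltage in overlapping 1 s bins, expresses it as percent change from the
baseline mean (stimulation bins masked), and correlates the fine-grained
(0.05 s) envelope with the cortical versus hippocampal LFP during the
seizure.  A more cortical than hippocampal correlation indicates the MUA
follows the local slow wave, not the seizure discharge.
"""

from ictal import SimConfig, generate_session, mua

session, truth = generate_session(SimConfig(seed=5, signals=("ofc_lfp", "hc_ipsi", "mua")))

hp = mua.mua_highpass(session.signals["mua"])
vrms = mua.compute_vrms(hp, bin_width_s=1.0, step_s=0.5)
_, _, period_pct = mua.vrms_percent_change(vrms, truth.epochs, session.annotation)
for period, pct in period_pct.items():
    print(f"{period:16s} V_RMS change {pct:+6.1f} %")

corr = mua.updown_correlation(
    session.signals["mua"], session.signals["ofc_lfp"], session.signals["hc_ipsi"],
    truth.epochs.ictal,
)
print(f"ictal envelope correlation: r(MUA, OFC) = {corr.r_mua_ofc:+.3f}, "
      f"r(MUA, HC) = {corr.r_mua_hc:+.3f}  (n = {corr.n_samples} samples)")
print("the negative ictal change reflects the up/down gating of firing.")
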