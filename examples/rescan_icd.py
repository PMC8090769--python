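"""Test-retest reproducibility of phantom SPECTRE maps.

Simulates a small cohort in which each subject has an individually tilted
corridor ('anatomy') and two scans differing by tensor noise, then scores
the maps with the intraclass-distance index: 100 % means within-subject
re-scan maps are identical relative to between-subject differences.
"""

from spectremri import compute_icd, simulate_rescan_study

for s in (0.05, 0.2):
    rs = simulate_rescan_study(n_subjects=5, tracking_noise=s, n_seeds=40, seed=11)
    res = compute_icd(rs)
    print(f"tracking noise s = {s:>4}: icd = {res.icd:5.1f} %  "
          f"(intra {res.intra_sum:.0f} / inter {res.inter_sum:.0f}, "
          f"{res.n_subjects} subjects)")
print("\nlower direction noise makes maps more reproducible (higher icd): "
      "the same robustness ordering seen across trackers on clinical "
      "re-scan data.")
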