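"""Reproduce the in-silico ERNA scenario battery.

Runs the STN-GPe mesocircuit under four conditions and prints the
P2 dynamics ratio (mean peak amplitude at pulses 40-45 over the first
pulse) of the inhibitory-conductance ERNA proxy.  P2 growth (> 1)
appears only with high-frequency stimulation, resilient efferents and
intact GPe-GPe collaterals — the architecture claim of the model.
"""

from ernakit import run_scenario

for label in ("hfs_full", "lfs_20", "depressing_efferent", "no_gpe_gpe"):
    s = run_scenario(label, n_iterations=5, seed=0)
    print(f"{label:20s} P1 ratio {s.p1_ratio_mean:5.2f} +- {s.p1_ratio_sd:.2f}   "
          f"P2 ratio {s.p2_ratio_mean:5.2f} +- {s.p2_ratio_sd:.2f}   "
          f"GPe rate during train {s.gpe_rate_on_mean:5.1f} Hz")

print()
print("P2 ratio > 1 means the second evoked peak grows across the train")
print("(ERNA emergence); ~1 or below means the resonance does not build up.")
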