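"""Show how an expanded clone inflates the index of association.

Simulates a freely recombining haploid population, then oversamples its
most common sequence type 20-fold (an 'epidemic' clone). The isolate-level
I^S_A rises well above zero while the deduplicated ST-level value stays
near zero -- the same contrast the real dataset shows.
"""

import numpy as np

from uzonmlsa import i_sa, i_sa_significance, make_regimes, simulate

for regime in ("panmictic_recombining", "epidemic", "clonal"):
    cfg = make_regimes()[regime]
    res = simulate(cfg)
    profiles = res.table.profiles_array()
    iso = i_sa(profiles)
    st = i_sa(np.unique(profiles, axis=0))
    sig = i_sa_significance(profiles, resamples=999, seed=cfg.seed)
    print(f"{regime:24s} n={len(profiles):3d}  "
          f"I^S_A(isolates)={iso.i_sa: .3f} (P={sig.p_value:.3f})  "
          f"I^S_A(unique STs)={st.i_sa: .3f}")
print("\nFree recombination gives I^S_A ~ 0; clonality gives a significantly")
print("positive value at both levels; an epidemic clone inflates only the")
print("isolate-level statistic.")
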