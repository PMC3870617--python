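"""Simulate a serum-miRNA study and call differential miRNAs.

Generates the default synthetic design (7 controls, three 3-patient
syndrome groups, 40 planted DE miRNAs per group at |log2FC| = 2) and runs
the random-variance-model moderated t-test with the FC > 1.5 & P < 0.05
conjunction rule, then scores the calls against the planted truth.
"""

from syndromirnet import SimulationConfig, differential_mirnas, simulate_all

sim = simulate_all(SimulationConfig(seed=1))
m, truth = sim["expression"], sim["truth"]
print(f"matrix: {m.values.shape[0]} miRNAs x {m.values.shape[1]} samples")

for group in ("LGDHS", "LDSDS", "LKYDS"):
    de = differential_mirnas(m, group, "Normal")
    called = set(de.index[de["significant"]])
    planted = truth.de_ids(group)
    tp = len(called & planted)
    print(f"{group} vs Normal: {len(called)} significant miRNAs "
          f"({tp}/{len(planted)} planted recovered, "
          f"{len(called) - tp} false positives)")

# The recovered fraction shows the moderated test's power at n = 3 vs 7;
# false positives reflect the conjunction rule's ~5% joint error rate.
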