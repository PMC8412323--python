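"""Multi-step model: a 3-switch lock-in gate on the road to resistance.

A sensitive->resistant conversion now requires three switch events to
complete.  With p_off = 0 the ladder only moves forward (lock-in); with
p_off > 0 any on-switch can flip back off, interrupting the transition.
Expected switch firings per conversion: 3 (forward), 9 (p_off=0.5),
51 (p_off=0.8) — the source of the graded reduction printed below.
"""

from epilock import SwitchChain, preset_scenario, reduction_percent, run_ensemble

N = 500
preset = preset_scenario("drug_resistant_stable")

ensembles = {}
for i, p_off in enumerate((0.0, 0.5, 0.8)):
    ensembles[p_off] = run_ensemble(
        preset, mode="multi_step", switch=SwitchChain(p_off),
        n_replicates=N, report_times=(6.0,), seed=10 + i,
    )
    mean, sd, _ = ensembles[p_off].group_stats(("G-R", "GS-R"), 6.0)
    print(f"p_off={p_off:.1f}: resistant cells at day 6 = {mean:6.1f} +- {sd:.1f}")

for p_off in (0.5, 0.8):
    red = reduction_percent(ensembles[0.0], ensembles[p_off], at=6.0)
    print(f"reduction at p_off={p_off}: {red:.1f}% vs forward lock-in")
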