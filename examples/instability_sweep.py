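"""Sweep the switch-off probability: the dose-response of instability.

Reproduces the inverse relationship between the probability of a lock-in
switch turning off and the day-6 resistant population of the multi-step
model.  Optionally saves a figure next to this script.
"""

import sys

from epilock import instability_sweep

table = instability_sweep(
    (0.0, 0.2, 0.4, 0.5, 0.6, 0.8), n_replicates=300, seed=5
)
print(table.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
base = table["mean_resistant"].iloc[0]
print("\nreduction vs p_off=0:",
      ", ".join(f"{p:.1f}->{100 * (1 - m / base):.0f}%"
                for p, m in zip(table["p_off"][1:], table["mean_resistant"][1:])))

if "--plot" in sys.argv:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.errorbar(table["p_off"], table["mean_resistant"], yerr=table["sd"],
                marker="o", capsize=3)
    ax.set_xlabel("switch-off probability p_off")
    ax.set_ylabel("resistant cells at day 6 (mean ± SD)")
    fig.tight_layout()
    fig.savefig("instability_sweep.png", dpi=150)
    print("wrote instability_sweep.png")
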