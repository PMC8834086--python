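"""Leave-one-out robustness: recognize a trajectory absent from the library.

Each of the 14 trajectories is observed while the library holds only the
other 13. Rationality-based recognition (mirroring) ignores the library;
LRGR matches through the closest known plan; the idealized library matcher
requires an exact tube match and often never commits.
"""

import pandas as pd

from goalrec import leave_one_out, make_berkovitz_scenario

scenario = make_berkovitz_scenario()

frames = []
for alg in ("mirroring", "lrgr", "ideal"):
    df = leave_one_out(alg, scenario, step_fraction=0.05)
    frames.append(df)
table = pd.concat(frames).pivot_table(
    index=["goal_id", "curve_index"],
    columns="algorithm",
    values="convergence_fraction",
    dropna=False,
)
print("convergence fraction per held-out trajectory (NaN = never converged):")
print(table.round(2).to_string())
print(
    "\nLRGR converges on every held-out trajectory by detouring through the"
    " closest library plan; the idealized matcher finds no exact match and"
    " fails to commit, while mirroring is unaffected by the library."
)
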