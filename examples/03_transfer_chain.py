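"""Mobility ratios and the accumulator / indicator / excluder verdict.

Builds the compartment-vs-topsoil mobility-ratio summary from the bundled
survey tables, then prints the per-element means, their behaviour class
and the descending element ranking for the root/soil step.
"""

import warnings

import pandas as pd

import vinemetals as vm

records = pd.concat([vm.load_table1(), vm.load_table2(), vm.load_table3()],
                    ignore_index=True)

print("Root/soil mobility ratio per element (mean over cultivars):")
means = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for el in vm.ELEMENTS:
        summary = vm.tf_chain(records, el, pairs=(("root", "soil"),),
                              soil_reference="topsoil_0_20")[0]
        means[el] = summary.mean
        print(f"  {el:<3} mean={summary.mean:6.3f}  RSD%={summary.rsd_pct:6.1f}  "
              f"-> {summary.classification}")

ranking, _ = vm.rank_elements(means)
print(f"Ranking: {ranking}")
print("Means above ~1.25 mark elements the vine enriches in its roots")
print("(accumulator); clearly below 0.75, elements it excludes.")
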