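"""Grade concentrations against regulatory limits.

Soil values are compared with the tiered national limits (normal / alert /
intervention, by land-use susceptibility); wine values with maximum
permissible limits.  A tier is assigned only when its bound is strictly
exceeded.
"""

import vinemetals as vm

thresholds = vm.load_soil_thresholds()
mpl = vm.load_beverage_mpl()

res = vm.grade_soil(("Cu", 3165.26), thresholds, land_use="susceptible")
print(f"Soil Cu 3165.26 mg/kg -> {res.tier} "
      f"({res.ratio_to_limit:.0f}x the normal value)")

res = vm.grade_beverage(("Cu", 1.47), mpl, matrix="wine")
print(f"Wine Cu 1.47 mg/L -> {res.tier} (limit 1 mg/L)")

wine = vm.load_table3()
cd = wine[(wine["compartment"] == "wine") & (wine["element"] == "Cd")]
above = sum(vm.grade_beverage(r, mpl).tier == "above_mpl" for _, r in cd.iterrows())
print(f"Wine Cd: {above} of {len(cd)} samples above the 0.01 mg/L limit")
print("(the three background-area samples are below the quantification limit).")
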