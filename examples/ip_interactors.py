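"""Differential interactor calling from bait immunoprecipitation data.

Loads the packaged RELA co-IP example (MCF-7 cells, NF-κB inhibited vs
uninhibited; anti-RELA bait vs IgG control) and applies the standard
thresholds — log2 fold change above 0.58 (a 1.5-fold change) at q < 0.05 —
to call interactors and the interactions gained or lost upon inhibition.
"""

import cofracnet as cfn

data = cfn.load_rela_ip_example()

called = cfn.call_interactors(data["uninhibited_bait_vs_ctrl"])
print(
    f"{len(called)} of {len(data['uninhibited_bait_vs_ctrl'])} table proteins pass "
    "the bait-vs-control filter in uninhibited cells, e.g.: "
    + ", ".join(sorted(called)[:6])
)

up, down = cfn.compare_conditions(data["inhibited_vs_uninhibited_bait"])
print(f"\nbetween conditions: {len(up)} interactors up, {len(down)} down after inhibition")
print("lost upon NF-κB inhibition (binding decreased):", ", ".join(sorted(down)))

nfkbia = next(r for r in data["inhibited_vs_uninhibited_bait"] if r.protein == "NFKBIA")
print(
    f"\nNFKBIA binding to RELA after inhibition: log2FC = {nfkbia.log2fc:+.2f} "
    f"(q = {nfkbia.q:.3f})"
)
print(
    "The IκB super-repressor used to inhibit NF-κB is itself an NFKBIA "
    "variant, so increased NFKBIA-RELA binding is the expected on-target effect."
)
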