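"""Deterministic cost-utility analysis: QALYs, costs, ICER/dominance, NMB.

Runs every treatment of the bundled synthetic DME-like scenario through the
cohort engine and prints the incremental comparison of the intervention
against each comparator, in the shape of a published cost-effectiveness table.
"""

from retinaecon import full_cea
from retinaecon.fixtures import load_example
from retinaecon.reporting import components_table, incremental_table

ps = load_example("DME")
results, incrementals = full_cea(ps)

print(f"willingness to pay: {ps.settings.wtp_threshold:.0f} USD per QALY\n")
print(incremental_table(results, incrementals).to_string(index=False,
                                                         float_format=lambda x: f"{x:,.2f}"))
print()
print(components_table(results).to_string(index=False, float_format=lambda x: f"{x:,.2f}"))
print()
print("positive incremental cost = the comparator costs more than the intervention;")
print("'dominant' = the intervention is cheaper AND gains QALYs; NMB = WTP x dQALY + dCost.")
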