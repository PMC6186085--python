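"""Simulate three-valued steady states of the toy p53 network.

Computes the logical steady state under DNA damage OFF and ON (p53
wild-type), then the per-node model prediction E_mod between the two
scenarios: +1 predicted up-regulation after damage, -1 down, 0 unchanged.
"""

from p53netval import Scenario, compute_steady_state, derive_emod, toy_p53_network

net = toy_p53_network()
off = compute_steady_state(net, Scenario("wt", "OFF"))
on = compute_steady_state(net, Scenario("wt", "ON"))
emod = derive_emod(off, on)

print(f"{'node':<15}{'OFF':>6}{'ON':>6}{'E_mod':>7}")
for node in net.nodes:
    print(f"{node:<15}{off.states[node]:>6}{on.states[node]:>6}{emod[node]:>7}")

ups = sorted(g for g, v in emod.items() if v == 1)
downs = sorted(g for g, v in emod.items() if v == -1)
print(f"\npredicted up after DNA damage ({len(ups)}): {', '.join(ups)}")
print(f"predicted down after DNA damage ({len(downs)}): {', '.join(downs)}")
print("NaN states are 'undetermined': unforced by the damage input.")
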