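"""Replay the packaged therapist-client worked example.

The session log scripts how a therapist (Thera) reshapes a client's (Clive)
belief network: a distressing belief RAF forms from two memories, praise and
a modeled humor-reframe arrive by social transmission and inhibit it, and
two new RAFs (a joke, and the belief "I am funny") form by representational
redescription.  The script prints the client's impact-weight trajectory and
the final RAF structure.
"""

from rafnet import (
    BELIEF_STUPID,
    build_clive_thera,
    clive_thera_log,
    impact_trajectory,
    irr_rafs,
    max_raf,
    mind_to_system,
)

dyad = build_clive_thera()
client = dyad.client

print(f"client foodset F_C ({len(client.foodset)} items): {sorted(client.foodset)}")
print(f"client derived ¬F_C ({len(client.derived)} items): {sorted(client.derived)}")

print("\nimpact of the 'I am stupid' RAF after each step touching it:")
last = None
for step, impacts in impact_trajectory(clive_thera_log()):
    w = impacts.get(BELIEF_STUPID)
    if w is not None and w != last:
        print(f"  step {step:>4}: {w:.3f}")
        last = w

q = mind_to_system(client)
irr = irr_rafs(q, "exhaustive")
print(f"\nfinal maxRAF: {sorted(max_raf(q).subset)}")
print(f"irreducible RAFs ({len(irr)}): {[sorted(s) for s in irr]}")

# Expected: the belief RAF's weight falls 1.0 -> 0.5 -> 0.25 (praise at step 3,
# the joke at step 6b, each inhibitory), and the final mind holds exactly three
# irreducible RAFs — {r1}, {r2}, {r3} — whose union is the maxRAF.
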