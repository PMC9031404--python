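"""Detect the RAF structure of a small catalytic reaction system.

Builds the packaged minimal example — two memories (GC: a bad grade,
PC: a job rejection) redescribed into the belief "I am stupid" (b1C),
catalyzed by the 'moron' incident (mC) — and certifies that the single
reaction forms a RAF: it is catalyzed from the foodset and its reactants
are foodset-generated.
"""

from rafnet import all_sub_rafs, closure, is_raf, max_raf, parse_system

TEXT = """
F: GC, PC, mC
r1: GC + PC -> b1C
cat: mC r1
"""

q = parse_system(TEXT)
print(f"types X = {sorted(q.types)}")
print(f"foodset F = {sorted(q.foodset)}")

cl = closure(q)
print(f"closure of F under R: {sorted(cl.available)} (firing order {list(cl.order)})")

res = is_raf(q, {"r1"})
print(f"{{r1}} reflexively autocatalytic: {res.is_ra}   F-generated: {res.is_f_generated}")
print(f"{{r1}} is a RAF: {res.is_raf}")

print(f"maxRAF: {sorted(max_raf(q).subset)}")
print(f"all subRAFs: {[sorted(s) for s in all_sub_rafs(q)]}")

# Expected output: the closure adds b1C to the four starting types, and {r1}
# passes both RAF criteria, so the maxRAF is ['r1'] and it is the only subRAF —
# the smallest possible self-sustaining, collectively autocatalytic network.
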