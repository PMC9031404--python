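# A system with no RAF: r1's reactant b is neither food nor produced,
# and r2's catalyst c is only produced by r2 itself via unreachable b.
# format_version: 1
X: a, b, c, d
F: a
r1: b -> c
r2: b -> d
cat: a r1
cat: c r2
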