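# The minimal single-reaction RAF from the worked therapist-client example:
# two distressing memories (GC, PC) are redescribed into the belief
# "I am stupid" (b1C), catalyzed by the "moron" incident (mC).
# format_version: 1
X: GC, PC, b1C, mC
F: GC, PC, mC
r1: GC + PC -> b1C
cat: mC r1
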