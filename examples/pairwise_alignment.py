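"""Align two short chromatin state sequences and inspect the result.

Builds the canonical example pair abca / aba, runs the dynamic program at
the default parameters (mismatch penalty 1.5, deletion penalty 1, equal
state weights, end-anchored local score), and prints the alignment.
"""

from epialign import StateAlphabet, align, brute_force_align, format_alignment, from_letters

alpha = StateAlphabet.from_size(4)
s1 = from_letters("abca", alpha)
s2 = from_letters("aba", alpha)

aln = align(s1, s2)
print(format_alignment(aln, s1, s2, alphabet=alpha))
print()
print("status string F :", ",".join(aln.F))
print("index vector U1 :", aln.U1.tolist())
print("index vector U2 :", aln.U2.tolist())
print("exhaustive check:", brute_force_align(s1, s2))

# The score 5.0 decomposes as match(2) + match(2) + deletion(-1) + match(2):
# the third state of S1 ('c') is deleted, everything else matches.
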