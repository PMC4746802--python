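"""Score a single compound signature against a tiny ranked instance.

Builds a ten-gene instance by hand, scores three signatures sitting at the
top, the bottom, and spread through the ranking, and prints the signed KS
score with its two components.
"""

from reposcan import RankedInstance, ks_score

instance = RankedInstance(genes=tuple(f"g{i}" for i in range(1, 11)))

for label, genes in [
    ("top of the ranking ", {"g1", "g2"}),
    ("bottom of the ranking", {"g9", "g10"}),
    ("spread through it   ", {"g3", "g7"}),
]:
    s = ks_score(instance, genes)
    print(f"{label}: KS = {s.value:+.3f}  (a = {s.a:.3f}, b = {s.b:.3f}, t = {s.t})")

print()
print("Positive KS: the signature's genes crowd the top ranks (enrichment).")
print("Negative KS: they lag behind the uniform expectation; an exact a == b")
print("tie is scored -b, so only clear top-heavy signatures score positive.")
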