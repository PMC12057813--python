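"""Quality-aware minimizer seeds on a single read.

Builds a short read with one low-quality stretch, extracts canonical
(k, w)-minimizers, and shows which of them count as high-confidence seeds
(HCS): only seeds whose k bases are all likely correct (product of Phred
probabilities above T1) may enter a cluster representation.
"""

from seedclust import Read, SeedParams, canonical_minimizers, hcs_of, phred_to_prob

# 60 bp read: high quality (Q40, 'I') except a Q8 ('\'') stretch in the middle
sequence = "ACGTTAGCCATGGATCCGTAGCTTAACGGATCGTACCGGTTAGCATGCCGTAATCGGATC"
quality = "I" * 25 + "'" * 10 + "I" * 25
read = Read("example", sequence, quality)

params = SeedParams(k=7, w=5, canonical=True, t1=0.9)
seeds = canonical_minimizers(read, params)
high = hcs_of(seeds, params.t1)

print(f"read length {len(sequence)}, k={params.k}, w={params.w}, T1={params.t1}")
print(f"per-base correctness at Q40: {phred_to_prob(40):.5f}, at Q8: {phred_to_prob(8):.3f}")
print(f"{len(seeds)} minimizer seeds, {len(high)} high-confidence values:")
for s in seeds:
    tag = "HCS" if s.value in high else "   "
    print(f"  pos {s.position:2d}  confidence {s.confidence:.4f}  {tag}")
print(
    "\nSeeds overlapping the low-quality stretch fall below T1: a single "
    "Q8 base caps the 7-mer confidence near "
    f"{phred_to_prob(8):.2f}, so only the clean flanks contribute HCS."
)
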