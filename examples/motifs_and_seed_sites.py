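"""Scan extension sequences for 3'UTR regulatory motifs and miRNA seed sites.

The four built-in patterns are classical stability and polyadenylation
elements in a gapped IUPAC grammar (e.g. the mammalian polyA element
"A(A|U)UAAA 12.40 KKKKKKKKKK [5,0,0]": a hexamer, a 12-40 base gap, and a
GU-rich run tolerating 5 substitutions).  Seed sites count 8mer / 7mer-m8 /
7mer-A1 matches of a 7-base miRNA seed (positions 2-8).
"""

from utrx import BUILTIN_MOTIFS, count_motifs, count_seed_sites, extract_sequence
from utrx.simulate import SyntheticConfig, generate_dataset

bundle, truth = generate_dataset(SyntheticConfig(n_genes=200, rng_seed=0))
regions = [g.extension_region for g in truth.extension_genes
           if g.extension_region.length < 1000]
ext_seqs = [extract_sequence(bundle.sequences, r) for r in regions]
ig_seqs = [extract_sequence(bundle.sequences, r) for r in truth.intergenic_pool]

table = count_motifs({"extensions": ext_seqs, "intergenic": ig_seqs})
print("motif hits per kbp (extensions vs intergenic):")
for name in BUILTIN_MOTIFS:
    print(f"  {name:16s} {table.per_kbp('extensions', name):6.3f}"
          f"   {table.per_kbp('intergenic', name):6.3f}")
print("(the generator plants mammalian polyA instances in extensions,"
      " hence the enrichment there)")

# miRNA seed-site counting: let-7 family seed, positions 2-8
seed = "GAGGUAG"
target = "".join(ext_seqs)
counts = count_seed_sites(target, [seed])[seed]
print(f"\nlet-7 seed {seed} sites over {len(target)} bp of extension sequence:")
print(f"  8mer {counts['8mer']}  7mer-m8 {counts['7mer-m8']}"
      f"  7mer-A1 {counts['7mer-A1']}")
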