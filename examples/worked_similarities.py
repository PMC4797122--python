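"""Score one pair of toy SMILES strings with every similarity function.

Uses the two small strings OC(O)=O (carbonic-acid-like) and
CCCCC(O)=C4 and prints each kernel's value.  The whole-string kernels
see the atom-collapsed SMILES; the LINGO family additionally zeroes the
ring digit (C4 -> C0) so ring numbering cannot split otherwise equal
q-grams.  The TF cosine treats each molecule as a 'document' of
4-character LINGOs; with only these two molecules as the corpus, every
LINGO occurs somewhere, so the TF-IDF variant assigns weight only to
terms missing from one of them.
"""

import smilesim as sm

r1 = sm.make_record("SMI1", "OC(O)=O")
r2 = sm.make_record("SMI2", "CCCCC(O)=C4")
s1, s2 = r1.norm_smiles, r2.norm_smiles

print(f"comparing {s1!r} vs {s2!r}\n")
print(f"edit distance        {sm.edit_distance(s1, s2)}")
print(f"edit similarity      {sm.edit_similarity(s1, s2):.4f}")
print(f"NLCS                 {sm.nlcs(s1, s2):.4f}")
print(f"NMCLCS1              {sm.nmclcs1(s1, s2):.4f}")
print(f"NMCLCSn              {sm.nmclcsn(s1, s2):.4f}")
print(f"CLCS (0.33 weights)  {sm.clcs_similarity(s1, s2):.4f}")
print(f"substring kernel     {sm.substring_kernel(s1, s2):.0f}  (raw inner product)")
print(f"substring kernel     {sm.substring_kernel(s1, s2, normalize=True):.4f}  (cosine-normalized)")

p1, p2 = sm.extract_lingos(r1), sm.extract_lingos(r2)
print(f"LINGOsim (q=4)       {sm.lingosim(p1, p2):.4f}")

vocab = sm.build_vocabulary([p1, p2])
tf1, tf2 = sm.vectorize(p1, vocab, "tf"), sm.vectorize(p2, vocab, "tf")
print(f"TF cosine            {sm.cosine_similarity(tf1, tf2):.4f}")

for name in ("smifp34", "smifp38"):
    alpha = sm.get_alphabet(name)
    f1 = sm.compute_fingerprint(r1, alpha)
    f2 = sm.compute_fingerprint(r2, alpha)
    print(f"SMIfp CBD  ({name})  {sm.cbd_similarity(f1, f2):.4f}  (CBD={sm.city_block_distance(f1, f2)})")
    print(f"SMIfp Tanimoto ({name[-2:]}D) {sm.tanimoto_counts(f1, f2):.4f}")

print(
    "\nHigher means more similar for every row except the raw distances; "
    "the three LCS variants are ordered NMCLCS1 <= NMCLCSn <= NLCS by construction."
)
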