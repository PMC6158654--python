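"""Turn protein sequences into mixed g-gap dipeptide composition vectors.

Builds two short sequences, computes their 0-gap and 1-gap dipeptide
frequencies, and prints the non-zero entries of the mixed 800-dim vector.
"""

from idaod import ProteinRecord, ggap_frequencies, mixed_feature_vector
from idaod.features import DIPEPTIDES

records = [
    ProteinRecord("toy1", "ACDEFACD"),
    ProteinRecord("toy2", "WYWYWYWY"),
]

for rec in records:
    print(f"{rec.id}: {rec.residues} (L = {rec.length})")
    for g in (0, 1):
        prof = ggap_frequencies(rec, g)
        nz = {
            DIPEPTIDES[i]: round(float(f), 4)
            for i, f in enumerate(prof.frequencies) if f > 0
        }
        print(f"  g={g}: {prof.counts.sum()} pairs -> {nz}")
    v = mixed_feature_vector(rec)
    print(f"  mixed vector length {v.values.shape[0]}, "
          f"halves sum to {v.values[:400].sum():.1f} + {v.values[400:].sum():.1f}")
    print()

print("Each g-gap profile is a distribution over the 400 ordered residue")
print("pairs; the model input concatenates the g=0 and g=1 profiles.")
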