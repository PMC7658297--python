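"""Compare class-conditional triad content between the two classes.

Positives in the synthetic generator up-weight hydrophobic residues
(triad classes 1 and 2), so triads built from those classes should show
a positive mean difference (antioxidant minus non-antioxidant) — the
feature-contribution view of what the classifier exploits.
"""

from antioxseq import SyntheticDatasetSpec, extract_features, generate, group_feature_means

ds = generate(SyntheticDatasetSpec(n_pos=80, n_neg=80, enrichment=3.0, seed=11))
fm = extract_features(ds)

ct_names = [f for f in fm.feature_names if f.startswith("ct")]
df = group_feature_means(fm, ct_names)

hydro = [f"ct{a}{b}{c}" for a in (1, 2) for b in (1, 2) for c in (1, 2)]
frac_up = (df.loc[hydro, "difference"] > 0).mean()
print("triads over hydrophobic classes 1-2 with higher content in positives:"
      f" {frac_up:.0%} of {len(hydro)}")
print("\nlargest positive differences (positive-class enriched):")
print(df.sort_values("difference", ascending=False).head(5).round(4).to_string())
print("\nA positive 'difference' means the triad is more frequent in antioxidant")
print("(positive) sequences; hydrophobic-class triads dominate, mirroring the")
print("planted compositional signal.")
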