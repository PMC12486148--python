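"""Design promiscuous and selective binders by simulated annealing.

Two anti-correlated pseudo-materials make the two goals pull in opposite
directions: the promiscuous objective minimises the mean score over both
materials, the selective objective minimises the score difference
(target minus off-target).  Scoring uses the ground-truth landscapes
directly, so the campaign is fast; swap in `surrogate.scorer()` to design
against a trained model instead.
"""

import pepanneal as pa

family = pa.make_family(k=2, target_correlation=-0.8, shared_seed=17,
                        noise_sigma=0.0)
scorers = family.scorers()
a, b = family.labels()
schedule = pa.AnnealSchedule(steps=3000)  # desk-scale; the default is 21 525

for mode, materials in [("promiscuous", (a, b)), ("selective", (a, b))]:
    campaign = pa.run_campaign(scorers, pa.Objective(mode, materials),
                               schedule, n_runs=5, base_seed=1)
    top = campaign.values[:100]
    print(f"{mode}: {len(campaign)} unique designs, "
          f"top-100 objective {top.mean():.1f} +/- {top.std(ddof=1):.1f} "
          f"(best {top.min():.1f})")

    # Diverse panel for downstream validation: best-first greedy selection,
    # every pair at least 3 mutations apart, 12 candidates.
    panel = pa.select_diverse(list(zip(campaign.peptides, campaign.values)))
    print(f"  panel of {len(panel)}: {panel.peptides[0]} ... "
          f"{panel.peptides[-1]}")

    profile = pa.composition_frequencies(campaign.peptides[:100])
    enriched = sorted(profile.as_dict().items(), key=lambda kv: -kv[1])[:3]
    print("  most frequent residues in top-100:",
          ", ".join(f"{aa} {f:.0%}" for aa, f in enriched))
# Selective campaigns reach much lower (better) score differences than the
# promiscuous campaign's designs would show, since the anti-correlated
# landscapes let single sequences trade one material against the other.
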