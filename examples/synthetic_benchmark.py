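"""Synthetic domains with planted modifications, and t-test calibration.

Generates 50 domains with threefold enrichment of K/R modifications inside
the membrane-binding site windows, recomputes each domain's MET-stop score
from the emitted PTM table, compares against the planted truth, and then
estimates the paired t-test's type-I error (no enrichment) and power
(threefold enrichment) over many replicates.
"""

from metstop import SynthConfig, compute_stop_score, gen_domain_set, gen_ptm_table
from metstop.scoring import stop_weight
from metstop.synth import paired_t_rejection_rate

config = SynthConfig(n_domains=50, enrichment=3.0, seed=42)
domain_set = gen_domain_set(config)
records = gen_ptm_table(domain_set)
print(f"{config.n_domains} domains, {len(records)} planted modifications")

by_domain: dict[str, list] = {}
for rec in records:
    by_domain.setdefault(rec.protein, []).append(rec)
mismatches = 0
for name, seq in domain_set.sequences.items():
    score = compute_stop_score(seq, by_domain.get(name, []), domain_set.windows)
    expected = sum(
        stop_weight(m["study_count"])
        for m in domain_set.truth["modifications"]
        if m["domain"] == name and m["region"] != "outside"
    )
    mismatches += score.total != expected
print(f"stop-score recomputation mismatches vs planted truth: {mismatches}")

null_rate = paired_t_rejection_rate(SynthConfig(enrichment=1.0, seed=1), n_replicates=1000)
power = paired_t_rejection_rate(SynthConfig(enrichment=3.0, seed=2), n_replicates=500)
print(f"paired t-test rejection rate under the null (rho=1): {null_rate:.3f}")
print(f"power at threefold enrichment (rho=3):              {power:.3f}")
# The null rate should sit near the nominal 0.05; at rho=3 the inside-vs-
# outside difference in modification proportions is detected essentially
# always at these study conditions.
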