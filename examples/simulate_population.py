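"""Simulate a small F1 hybrid cross with indels and planted trait effects.

Builds two outbred parents, 120 F1 lines with paternal-only indels, and a
phenotype table whose traits carry planted allelic and dosage effects.
"""

from duoqtl.simulate import SimConfig, simulate_experiment

cfg = SimConfig(n_chrom=3, chrom_len=1_000_000, n_lines=120, deep_n=40,
                indel_rate=1.0, indel_size_range=(250_000, 500_000))
exp = simulate_experiment(cfg, seed=11)

pd_g, pn_g = exp.parents
print(f"heterozygous sites: Pd={pd_g.n_het_sites()}, Pn={pn_g.n_het_sites()}")
n_carriers = sum(1 for l in exp.lines if l.indels)
n_indels = sum(len(l.indels) for l in exp.lines)
dels = sum(1 for l in exp.lines for i in l.indels if i.kind == "deletion")
print(f"indel carriers: {n_carriers}/{len(exp.lines)} lines, "
      f"{n_indels} indels ({100 * dels / n_indels:.1f}% deletions)")
print(f"traits: {exp.phenotypes.traits}")
print(exp.phenotypes.values.describe().round(2).to_string())

# The parents' het-site counts emulate the tens of thousands of phased SNPs
# of a real outbred cross at desk scale; the deletion fraction reflects the
# bias of radiation-induced events toward loss.
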