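"""Characterize nuclear retained introns against the all-RI background:
splice-boundary composition, length, stem probability, and dinucleotide
enrichment.
"""
import isoloc as il

cfg = il.SimulationConfig(n_genes=90, event_mix={"RI": 1.0},
                          frac_switching_genes=0, mono_nuclear_frac=0,
                          ri_nuclear_frac=1 / 3, ri_short_len=150,
                          ri_bg_len=1500, seed=44)
models, truth = il.simulate_annotation(cfg)
genome = il.simulate_sequences(models, truth, cfg)
expr = il.simulate_expression(models, truth, cfg)

events, _ = il.extract_events(models)
psi = il.compute_delta_psi(events, expr, seed=0)
nuclear, all_ri = il.select_nuclear_ris(psi)
by_id = {e.event_id: e for e in events}
nuc_iv = il.ri_intron_intervals(nuclear, by_id)
all_iv = il.ri_intron_intervals(all_ri, by_id)

prof_n = il.profile_introns(nuc_iv, genome)
prof_a = il.profile_introns(all_iv, genome)
pn = il.profiles_table(prof_n)
pa = il.profiles_table(prof_a)
length = il.compare_feature(pn, pa, "length")
stem = il.compare_feature(pn, pa, "mean_stem_probability")
print(f"nuclear RIs: n={len(pn)}, mean length {pn['length'].mean():.0f} nt, "
      f"mean stem probability {pn['mean_stem_probability'].mean():.3f}")
print(f"all RIs:     n={len(pa)}, mean length {pa['length'].mean():.0f} nt, "
      f"mean stem probability {pa['mean_stem_probability'].mean():.3f}")
print(f"length Welch p = {length.p_value:.2g} (log10 scale); "
      f"stem Welch p = {stem.p_value:.2g}")

donor_n, acc_n, _ = il.boundary_matrices(nuc_iv, genome)
donor_a, acc_a, _ = il.boundary_matrices(all_iv, genome)
print(f"max per-position TV distance, donor boundary: "
      f"{il.tv_distance(donor_n, donor_a).max():.3f} "
      f"(GT consensus positions agree exactly; the rest is sampling "
      f"noise plus the planted GC shift)")
ratios = il.dinucleotide_enrichment(prof_n, prof_a)
print("GC-dinucleotide ratios (nuclear / all):",
      {d: round(ratios[d], 2) for d in ("GC", "CG", "GG", "CC")})
# nuclear RIs come out shorter, more structured and GC-richer than the
# background — the planted signature of nucleus-retained introns
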