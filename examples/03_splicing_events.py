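"""Classify the seven local splicing-event kinds and quantify ΔΨ.

Ψ = inclusion TPM / (inclusion + exclusion TPM) per fraction; ΔΨ =
Ψ_cytoplasm − Ψ_nucleus, so negative ΔΨ marks event forms retained in the
nucleus. Nuclear RIs are retained introns with ΔΨ < 0 at p < 0.05.
"""
import isoloc as il

cfg = il.SimulationConfig(n_genes=350, frac_switching_genes=0,
                          mono_nuclear_frac=0, ri_nuclear_frac=1.0,
                          psi_effect=0.4, seed=35)
models, truth = il.simulate_annotation(cfg)
expr = il.simulate_expression(models, truth, cfg)

events, residual = il.extract_events(models)
psi = il.compute_delta_psi(events, expr, seed=0)
print(f"events classified: {len(events)} ({len(residual)} residual)")
print(il.psi_by_kind(psi).to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))
nuclear, all_ri = il.select_nuclear_ris(psi)
print(f"nuclear RIs: {len(nuclear)} of {len(all_ri)} quantified RIs")
# only the RI row has a strongly negative median ΔΨ: the generator planted
# nuclear bias exclusively in retained introns, and the classifier and
# quantification recover that kind-specific pattern
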