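"""Generate a synthetic IT/PT cohort and run the full comparison suite.

The generator mirrors the study conditions (zero-ipsi inflation 0.10,
contra-targeting probability 0.74 for IT neurons; wider IT spreads than PT).
The suite then asks the scientific questions of the analysis: do IT and PT
neurons differ in (log) ipsilateral end-point counts, in the proportion with
more than 50 end-points (chi-square + phi), and in spatial spread (Welch +
Cohen's d), and does spread scale with count (correlation/regression)?
"""

from csmorph import default_study_groups, generate_cohort, make_atlas, run_compare, run_extract

atlas = make_atlas()
records, truth = generate_cohort(default_study_groups(n_it=80, n_pt=30), seed=42, atlas=atlas)
table, errors = run_extract(records, policy=atlas.policy, ontology=atlas.ontology)
report = run_compare(table)

c = report.counts
print(f"cohort: {c['it_total']} IT, {c['pt_total']} PT "
      f"({c['it_no_ipsi']} IT without ipsilateral end-points, "
      f"{c['it_no_contra']} without contralateral)")

for name in ("ln n_ipsi: IT vs PT", "sd_x: IT vs PT", "sd_dist: IT vs PT"):
    comp = report.get("welch", name)
    r = comp.result
    print(f"[welch] {name:24s} n={comp.n1}/{comp.n2}  t={r.t:7.3f}  p={r.p:.2e}  d={r.d:.2f}")

chi = report.get("chi2", "> 50 ipsi: IT vs PT")
print(f"[chi2 ] >50 ipsi IT vs PT       table={chi.result.table}  "
      f"chi2={chi.result.chi2:.2f}  p={chi.result.p:.3f}  phi={chi.result.phi:.2f}")

corr = report.get("corr", "sd_x ~ ln n_ipsi: IT")
r = corr.result
print(f"[corr ] sd_x ~ ln n_ipsi (IT)   r={r.r:.2f}  p={r.p_r:.2e}  "
      f"slope={r.slope:.1f} um per log unit")
print("A positive d (and phi > 0) with small p means the IT terminal fields are")
print("detectably wider / more numerous than PT ones under these generating laws.")
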