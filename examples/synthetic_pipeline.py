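"""End-to-end drug-target interaction prediction on synthetic data.

Generates a planted-cluster study (60 drugs, 30 targets, 3 clusters),
runs repeated cross-validated WNN-GIP with two different compound
kernels, and compares them with a paired t-test on matched folds.
Drugs in a held-out fold are treated as brand-new compounds: their
interaction rows are hidden and their profiles imputed from chemically
similar training drugs, so AUCs measure true new-drug generalization.
"""

import smilesim as sm

spec = sm.SyntheticSpec(seed=0)
records, clusters, network, target_sim = sm.generate_bundle(spec)
print(
    f"study: {spec.n_drugs} drugs x {spec.n_targets} targets, "
    f"{int(network.adjacency.sum())} interactions "
    f"({network.adjacency.mean():.1%} density)\n"
)

results = {}
for name in ("lingosim", "tfidf-cosine"):
    res = sm.cross_validate(
        network, records, sm.get_kernel(name), target_sim,
        n_folds=5, n_repeats=5, seed=1,
    )
    results[name] = res
    print(
        f"{name:14s} AUC-ROC {res.mean_auc_roc:.3f} ({res.std_auc_roc:.3f})   "
        f"AUC-PR {res.mean_auc_pr:.3f} ({res.std_auc_pr:.3f})   "
        f"[{len(res.per_fold_auc_roc)} folds]"
    )

t, p, sig = sm.paired_ttest(results["lingosim"], results["tfidf-cosine"])
verdict = "significant" if sig else "not significant"
print(f"\npaired t-test on per-fold AUC-ROC: t={t:.2f}, p={p:.3f} ({verdict} at alpha=0.05)")
print(
    "AUC-ROC well above 0.5 shows the kernels recover the planted "
    "cluster structure; random scoring would sit at 0.5."
)
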