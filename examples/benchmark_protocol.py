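"""Benchmark evaluation protocol for externally supplied data sets.

The published drug-target benchmarks (enzyme, ion channel, GPCR,
nuclear receptor) and their 2D SIMCOMP similarity matrices must be
downloaded separately; absolute AUC values on them also depend on
predictor hyperparameters that are configuration, not code.  This
script therefore reproduces the *protocol* — 5 repetitions of 5-fold
cross-validation over drugs for each compound kernel, plus the
TF-IDF/SIMCOMP composite when a 2D matrix is supplied — on whatever
files you pass in:

    python examples/benchmark_protocol.py \
        --drugs drugs.tsv --adjacency adjacency.tsv \
        --target-sim target_sim.tsv [--simcomp simcomp.tsv] [--seed 1]

Run without arguments it demonstrates the identical protocol on a
small synthetic stand-in study generated on the fly.
"""

import argparse
import tempfile
from pathlib import Path

import smilesim as sm

KERNELS = (
    ("edit", {}),
    ("nlcs", {}),
    ("clcs", {}),
    ("substring", {}),
    ("smifp-cbd", {"alphabet": "smifp34"}),
    ("smifp-tanimoto", {"alphabet": "smifp34"}),
    ("smifp-cbd", {"alphabet": "smifp38"}),
    ("smifp-tanimoto", {"alphabet": "smifp38"}),
    ("lingosim", {"q": 3}),
    ("lingosim", {"q": 4}),
    ("lingosim", {"q": 5}),
    ("tf-cosine", {}),
    ("tfidf-cosine", {}),
)


def run_protocol(drugs, adjacency, target_sim, simcomp=None, seed=1,
                 n_folds=5, n_repeats=5, kernels=KERNELS):
    """Repeated-CV comparison of compound kernels on one data set.

    Returns {label: CvResult}.  When a precomputed 2D similarity matrix
    is given, the TF-IDF + 2D composite (lambda = 0.5) is evaluated too
    and compared against the 2D matrix alone with a paired t-test.
    """
    corpus = sm.read_compound_file(drugs)
    network = sm.read_adjacency_tsv(adjacency)
    tsim = sm.read_similarity_tsv(target_sim)
    results: dict[str, sm.CvResult] = {}
    for name, params in kernels:
        label = name + ("".join(f" {k}={v}" for k, v in params.items()) if params else "")
        results[label] = sm.cross_validate(
            network, corpus, sm.get_kernel(name, **params), tsim,
            n_folds=n_folds, n_repeats=n_repeats, seed=seed,
        )
    if simcomp is not None:
        S2d = sm.read_similarity_tsv(simcomp).reorder(network.drug_ids)
        order = {r.id: r for r in corpus}
        ordered = [order[d] for d in network.drug_ids]
        for kname in ("tfidf-cosine", "lingosim"):
            Sf = sm.pairwise_matrix(ordered, sm.get_kernel(kname))
            mixed = sm.composite(S2d, Sf, lam=0.5)

            class _Precomputed:
                name = f"{kname}+2D"
                params = {"lambda": 0.5}

                def prepare(self, corpus_):
                    lut = {r.id: i for i, r in enumerate(ordered)}
                    return lambda a, b: mixed.values[lut[a.id], lut[b.id]]

            results[f"{kname}+2D"] = sm.cross_validate(
                network, ordered, _Precomputed(), tsim,
                n_folds=n_folds, n_repeats=n_repeats, seed=seed,
            )
    return results


def print_report(results):
    print(f"{'method':22s} {'AUC-ROC (std)':>16s} {'AUC-PR (std)':>16s}")
    for label, res in results.items():
        print(
            f"{label:22s} {res.mean_auc_roc:8.3f} ({res.std_auc_roc:.3f})"
            f" {res.mean_auc_pr:8.3f} ({res.std_auc_pr:.3f})"
        )


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--drugs")
    parser.add_argument("--adjacency")
    parser.add_argument("--target-sim", dest="target_sim")
    parser.add_argument("--simcomp", default=None)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--repeats", type=int, default=5)
    args = parser.parse_args(argv)

    if args.drugs:
        results = run_protocol(
            args.drugs, args.adjacency, args.target_sim, args.simcomp,
            seed=args.seed, n_repeats=args.repeats,
        )
    else:
        print("no input files given; demonstrating the protocol on a synthetic study\n")
        spec = sm.SyntheticSpec(n_drugs=30, n_targets=15, seed=args.seed)
        records, _, network, tsim = sm.generate_bundle(spec)
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            sm.write_compound_file(tmp / "drugs.tsv", records)
            sm.write_adjacency_tsv(tmp / "adjacency.tsv", network)
            sm.write_similarity_tsv(tmp / "target_sim.tsv", tsim)
            results = run_protocol(
                tmp / "drugs.tsv", tmp / "adjacency.tsv", tmp / "target_sim.tsv",
                seed=args.seed, n_repeats=2,
                kernels=(("edit", {}), ("lingosim", {"q": 4}), ("tfidf-cosine", {})),
            )
    print_report(results)
    return results


if __name__ == "__main__":
    main()
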