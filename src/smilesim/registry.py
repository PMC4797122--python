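"""Named kernel registry: map kernel names to pairwise scoring functions.

A :class:`KernelSpec` bundles a kernel name with its parameters and
knows how to *prepare* itself on a compound corpus.  Preparation matters
for the corpus-level kernels (TF and TF-IDF cosine need a vocabulary
built from the whole compound set) and lets per-compound work (LINGO
profiles, fingerprints) be cached once instead of per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from . import lingo as _lingo
from . import smifp as _smifp
from . import stringkernels as _sk
from .prep import CompoundRecord

PairFunc = Callable[[CompoundRecord, CompoundRecord], float]


@dataclass
class KernelSpec:
    """A registered kernel with resolved parameters."""

    name: str
    params: dict
    _factory: Callable[["KernelSpec", Sequence[CompoundRecord]], PairFunc] = field(
        repr=False
    )

    def prepare(self, corpus: Sequence[CompoundRecord]) -> PairFunc:
        """Precompute per-compound state and return the pair scorer."""
        return self._factory(self, corpus)


def _edit(spec: KernelSpec, corpus: Sequence[CompoundRecord]) -> PairFunc:
    return lambda a, b: _sk.edit_similarity(a.norm_smiles, b.norm_smiles)


def _nlcs(spec: KernelSpec, corpus: Sequence[CompoundRecord]) -> PairFunc:
    return lambda a, b: _sk.nlcs(a.norm_smiles, b.norm_smiles)


def _clcs(spec: KernelSpec, corpus: Sequence[CompoundRecord]) -> PairFunc:
    weights = _sk.ClcsWeights(
        spec.params["w1"], spec.params["w2"], spec.params["w3"]
    )
    return lambda a, b: _sk.clcs_similarity(a.norm_smiles, b.norm_smiles, weights)


def _substring(spec: KernelSpec, corpus: Sequence[CompoundRecord]) -> PairFunc:
    min_len = spec.params["min_len"]
    normalize = spec.params["normalize"]
    return lambda a, b: _sk.substring_kernel(
        a.norm_smiles, b.norm_smiles, min_len=min_len, normalize=normalize
    )


def _lingosim(spec: KernelSpec, corpus: Sequence[CompoundRecord]) -> PairFunc:
    q = spec.params["q"]
    profiles = {r.id: _lingo.extract_lingos(r, q) for r in corpus}
    return lambda a, b: _lingo.lingosim(profiles[a.id], profiles[b.id])


def _tf_cosine_factory(scheme: str):
    def factory(spec: KernelSpec, corpus: Sequence[CompoundRecord]) -> PairFunc:
        q = spec.params["q"]
        profiles = {r.id: _lingo.extract_lingos(r, q) for r in corpus}
        vocab = _lingo.build_vocabulary(list(profiles.values()))
        vectors = {
            cid: _lingo.vectorize(p, vocab, scheme) for cid, p in profiles.items()
        }
        return lambda a, b: _lingo.cosine_similarity(vectors[a.id], vectors[b.id])

    return factory


def _smifp_factory(measure: str):
    def factory(spec: KernelSpec, corpus: Sequence[CompoundRecord]) -> PairFunc:
        alphabet = _smifp.get_alphabet(spec.params["alphabet"])
        fps = {r.id: _smifp.compute_fingerprint(r, alphabet) for r in corpus}
        fn = _smifp.cbd_similarity if measure == "cbd" else _smifp.tanimoto_counts
        return lambda a, b: fn(fps[a.id], fps[b.id])

    return factory


_REGISTRY: dict[str, tuple[Callable, dict]] = {
    "edit": (_edit, {}),
    "nlcs": (_nlcs, {}),
    "clcs": (_clcs, {"w1": 0.33, "w2": 0.33, "w3": 0.33}),
    # normalized by default here: raw inner products are not comparable
    # across molecule sizes inside a similarity matrix
    "substring": (_substring, {"min_len": 2, "normalize": True}),
    "lingosim": (_lingosim, {"q": _lingo.DEFAULT_Q}),
    "tf-cosine": (_tf_cosine_factory("tf"), {"q": _lingo.DEFAULT_Q}),
    "tfidf-cosine": (_tf_cosine_factory("tf-idf"), {"q": _lingo.DEFAULT_Q}),
    "smifp-cbd": (_smifp_factory("cbd"), {"alphabet": "smifp34"}),
    "smifp-tanimoto": (_smifp_factory("tanimoto"), {"alphabet": "smifp34"}),
}


def kernel_names() -> list[str]:
    return sorted(_REGISTRY)


def get_kernel(name: str, **params) -> KernelSpec:
    """Look up a kernel by name, overriding default parameters.

    Raises ``KeyError`` naming the kernel if it is not registered, and
    ``ValueError`` for parameters the kernel does not accept.
    """
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown kernel {name!r}; available: {', '.join(kernel_names())}"
        )
    factory, defaults = _REGISTRY[name]
    unknown = set(params) - set(defaults)
    if unknown:
        raise ValueError(f"kernel {name!r} does not accept parameters {sorted(unknown)}")
    resolved = {**defaults, **params}
    return KernelSpec(name=name, params=resolved, _factory=factory)
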