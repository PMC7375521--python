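"""Shared helpers for the test suite."""
from isofox.samples import CollagenSample, Period


def make_sample(lab_id="X-1", cn=3.3, n_coll=14.0, d13C=-20.0, d15N=5.0, **kw):
    return CollagenSample(lab_id=lab_id, period=Period.MP, site="HF",
                          taxon="Vulpes vulpes", cn_ratio=cn,
                          pct_N_coll=n_coll, d13C=d13C, d15N=d15N, **kw)
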