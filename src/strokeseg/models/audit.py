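"""Parameter accounting: engine-reported counts vs the closed-form tables.

``count_parameters`` reads the sizes of the arrays a built network actually
allocates; the model's ``spec`` computes the same totals from the k*k*C_in*
C_out (+bias) and 2C-per-normalisation formulas without touching the engine.
``verify_parameter_counts`` requires the two routes to agree layer by layer
and raises naming the first differing layer otherwise.
"""

from __future__ import annotations

import pandas as pd

from ..errors import ArchitectureError
from .base import Network
from .spec import ParamCountReport


def count_parameters(model: Network) -> ParamCountReport:
    """Count trainable / non-trainable parameters from the network's arrays."""
    rows = [{"layer": name,
             "trainable": layer.n_trainable(),
             "non_trainable": layer.n_non_trainable()}
            for name, layer in model.layers.items()]
    df = pd.DataFrame(rows, columns=["layer", "trainable", "non_trainable"])
    return ParamCountReport(trainable=int(df.trainable.sum()),
                            non_trainable=int(df.non_trainable.sum()),
                            per_layer=df)


def verify_parameter_counts(model: Network) -> ParamCountReport:
    """Check engine counts against the closed-form table, layer by layer."""
    report = count_parameters(model)
    engine = {r.layer: (r.trainable, r.non_trainable) for r in report.per_layer.itertuples()}
    for rec in model.spec.records:
        if rec.trainable == 0 and rec.non_trainable == 0:
            continue
        got = engine.get(rec.name)
        if got is None:
            raise ArchitectureError(f"layer {rec.name!r} in the closed-form table "
                                    "has no counterpart in the built network")
        if got != (rec.trainable, rec.non_trainable):
            raise ArchitectureError(
                f"layer {rec.name!r}: engine counts {got} differ from "
                f"closed-form ({rec.trainable}, {rec.non_trainable})")
    if (report.trainable, report.non_trainable) != (model.spec.trainable, model.spec.non_trainable):
        raise ArchitectureError(
            f"totals differ: engine ({report.trainable}, {report.non_trainable}) vs "
            f"closed-form ({model.spec.trainable}, {model.spec.non_trainable})")
    return report
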