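import random

import pytest

from vitinom.locus_id import LocusID, ObjectType


@pytest.fixture
def id_generator():
    """Seeded generator of random valid locus identifiers."""

    def make(seed: int, n: int):
        rng = random.Random(seed)
        out = []
        for _ in range(n):
            object_type = rng.choice(list(ObjectType))
            variant = None
            if rng.random() < 0.4:
                letters = "".join(rng.choices("abcdefghij",
                                              k=rng.randint(0, 3)))
                digits = ""
                if object_type.allows_splice_variant and rng.random() < 0.7:
                    digits = str(rng.randint(1, 12))
                variant = letters + digits or "a"
            out.append(LocusID(
                taxon=rng.choice(["VITVI", "VITVBR", "VITRI"]),
                chromosome=rng.randint(0, 19),
                object_type=object_type,
                numeric_code=rng.randint(1, 99999),
                variant=variant,
                version=rng.randint(1, 9) if rng.random() < 0.3 else None,
            ))
        return out

    return make
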