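import numpy as np
import pandas as pd
import pytest

from oryzabran import AbundanceMatrix, AnnotationCatalog, MetaboliteAnnotation


@pytest.fixture
def toy_abundance() -> AbundanceMatrix:
    """3 metabolites x 4 cultivars, one missing cell."""
    df = pd.DataFrame(
        {
            "cv1": [2.0, 1.0, 1.0],
            "cv2": [4.0, 1.0, 3.0],
            "cv3": [6.0, 1.0, np.nan],
            "cv4": [8.0, 1.0, 5.0],
        },
        index=["alpha", "beta", "gamma"],
    )
    return AbundanceMatrix(df)


@pytest.fixture
def toy_catalog() -> AnnotationCatalog:
    return AnnotationCatalog(
        [
            MetaboliteAnnotation("alpha", "lipids", "free fatty acid"),
            MetaboliteAnnotation("beta", "lipids", "oxylipins"),
            MetaboliteAnnotation("gamma", "amino acids", "serine family"),
        ]
    )
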