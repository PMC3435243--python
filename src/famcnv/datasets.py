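"""Bundled example data.

``candidate_evidence_table`` returns the published multi-evidence table for
25 left-sided CHD candidate genes (in-silico prioritization p-value, SAGE
outflow-tract fold enrichment, curated in-situ expression flag, transmission
pattern and genomic location).  It drives the worked example in the README
and the regression tests of the 2-of-3 candidate rule; ``nd``/``N/A`` mark
evidence that was not determined.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

_CANDIDATE_EVIDENCE_TSV = """\
gene	fusion_p	sage_fold	expression_flag	transmission	location
ANG/RNASE4	0.000376	nd	+	inherited	14q11.2
MAPK7	0.000122	8.15	-	de_novo	17p11.2
NCOR1	0.000937	nd	+	de_novo	17p11.2
ADORA2B	0.00379	nd	+	de_novo	17p11.2
MFAP4	0.00288	11.64	+	de_novo	17p11.2
COPS3	0.00379	nd	+	de_novo	17p11.2
FLII	0.00187	nd	+	de_novo	17p11.2
MSX1	0.0049	7.36	N/A	de_novo	4p16
SREBF1	0.00786	nd	+	de_novo	17p11.2
SMC1A	0.00906	nd	+	inherited	Xp11.22
LIMS1	0.00496	nd	+	inherited	2q12
CACNA1C	0.00734	nd	+	unknown	12p13
CRMP1	0.0156	10.96	-	de_novo	4p16
RASD1	0.0107	12.83	-	de_novo	17p11.2
ERCC5	0.0139	5.65	-	inherited	13q33
ULK2	0.0287	nd	+	de_novo	17p11.2
PLA2G12A	0.0409	3.61	-	unknown	10q22
NGEF	0.0454	nd	+	inherited	2q37
GRPEL1	0.11	3.10	+	de_novo	4p16
PRPSAP2	0.34	3.49	+	de_novo	17p11.2
MTHFD2	0.84	6.14	+	de_novo	2p13
EVC2	0.74	6.19	+	de_novo	4p16
CTHRC1	0.17	27.85	+	de_novo	8q22
ITGA10	0.00348	nd	+	de_novo	1q21
HSD17B10	0.0281	nd	+	inherited	Xp11.22
"""


def candidate_evidence_table() -> pd.DataFrame:
    """The 25-gene candidate evidence table as a DataFrame.

    ``fusion_p`` is numeric; ``sage_fold`` is numeric with NaN where not
    determined; ``expression_flag`` keeps ``+``/``-`` and NaN where no in-situ
    slide was available.
    """
    df = pd.read_csv(StringIO(_CANDIDATE_EVIDENCE_TSV), sep="\t")
    df["fusion_p"] = pd.to_numeric(df["fusion_p"])
    df["sage_fold"] = pd.to_numeric(df["sage_fold"], errors="coerce")
    df.loc[~df["expression_flag"].isin(["+", "-"]), "expression_flag"] = pd.NA
    return df


# Lesion-category counts of the example affected cohort (n = 174), used by
# the phenotype-summary worked example.
EXAMPLE_LESION_COUNTS = {
    "isolated aortic stenosis": 19,
    "isolated aortic root or ascending aorta dilation": 20,
    "isolated BAV": 17,
    "isolated mitral valve defect": 13,
    "isolated CoA": 5,
    "more than one LS-CHD lesion": 41,
    "LS-CHD lesion and additional CVM": 59,
}
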