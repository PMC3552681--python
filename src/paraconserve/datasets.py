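"""Bundled reference dataset: 16S rRNA copy numbers for 22 cyanobacteria.

A published survey of the 22 fully sequenced cyanobacterial genomes
available on GenBank (as of August 2011), recording for each strain its
differentiation group (G0 no differentiation, G1 circadian control only,
G2 reversible differentiation, G3 terminal differentiation), genome size
in Mb, the number of annotated 16S rRNA gene copies, and the GenBank
accession.  The 48 16S gene copies across these genomes and the
copy-number/morphotype correlation computed from this table are the
desk-scale reference values the package's acceptance checks recompute.
"""

from __future__ import annotations

import io

import pandas as pd

_CYANO_16S_TSV = """\
species\tgroup\tgenome_size_mb\tn_16s_copies\taccession
Acaryochloris marina MBIC11017\tG1\t8.36\t2\tCP000828.1
Anabaena variabilis ATCC 29413\tG3\t7.10\t4\tCP000117.1
Arthrospira platensis NIES 39\tG1\t6.80\t2\tAP011615
Cyanothece sp. PCC 7424\tG1\t6.52\t3\tCP001291.1
Cyanothece sp. PCC 8801\tG1\t4.81\t2\tCP001287.1
Gloeobacter violaceus PCC 7421\tG0\t4.70\t1\tBA000045.2
Microcystis aeruginosa NIES-843\tG1\t5.80\t2\tAP009552.1
Nostoc azollae 0708\tG3\t5.53\t4\tCP002059.1
Nostoc punctiforme PCC 73102\tG3\t9.01\t4\tCP001037.1
Nostoc sp. PCC 7120\tG3\t7.20\t4\tBA000019.2
Prochlorococcus marinus MIT 9211\tG0\t1.70\t1\tCP000878.1
Prochlorococcus marinus MIT 9303\tG0\t2.70\t2\tCP000554.1
P. marinus subsp. pastoris str. CCMP1986 (MED)\tG0\t1.70\t1\tBX548174.1
Synechococcus elongatus PCC 6301\tG1\t2.70\t2\tAP008231.1
Synechococcus sp. JA-3-3Ab\tG1\t2.90\t2\tCP000239.1
Synechococcus sp. PCC 7002\tG1\t3.40\t2\tCP000951.1
Synechococcus sp. RCC307\tG1\t2.20\t1\tCT978603.1
Synechococcus sp. WH 7803\tG1\t2.40\t2\tCT971583.1
Synechocystis sp. PCC 6803\tG1\t3.97\t2\tBA000022.2
Thermosynechococcus elongatus BP-1\tG1\t2.59\t1\tBA000039.2
Trichodesmium erythraeum IMS101\tG2\t7.80\t2\tCP000393.1
Cyanobacterium UCYN-A\tG0\t1.40\t2\tCP001842.1
"""


def cyanobacteria_16s() -> pd.DataFrame:
    """The 22-strain cyanobacterial 16S copy-number table."""
    return pd.read_csv(io.StringIO(_CYANO_16S_TSV), sep="\t")
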