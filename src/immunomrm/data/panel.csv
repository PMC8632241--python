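gene_symbol,peptide_modified_sequence,accession,description,status,spike_multiplier,heavy_spike_conc
ADAM17,VDNEELLPK,P78536,"ADAM metallopeptidase domain 17",active,10,200.0
ANXA1,AAYLQETGKPLDETLK,P04083,"annexin A1",active,1,200.0
ANXA1,GVDEATIIDILTK,P04083,"annexin A1",active,1,200.0
ARG2,TFDLLIGK,P78540,"arginase 2",active,1,200.0
ATM,NLS[ph]DIDQSFNK,Q13315,"ATM serine/threonine kinase",active,1,200.0
ATM,NLSDIDQSFNK,Q13315,"ATM serine/threonine kinase",active,1,200.0
ATM,SLEIS[ph]QSYTTTQR,Q13315,"ATM serine/threonine kinase",active,1,200.0
ATM,SLEISQSYTTTQR,Q13315,"ATM serine/threonine kinase",active,1,200.0
CCL5,EYFYTSGK,P13501,"C-C motif chemokine ligand 5",active,1,200.0
CD14,FPAIQNLALR,P08571,"CD14 molecule",active,1,200.0
CD163,LVDGVTEC[cam]SGR,Q86VB7,"CD163 molecule",active,10,200.0
CD274,NIIQFVHGEEDLK,Q9NZQ7,"CD274 molecule",active,1,200.0
CD33,ILIPGTLEPGHSK,P20138,"CD33 molecule",active,1,200.0
CD40,SC[cam]SPGFGVK,P25942,"CD40 molecule",active,1,200.0
CD40,YC[cam]DPNLGLR,P25942,"CD40 molecule",active,1,200.0
CD47,STVPTDFSSAK,Q08722,"CD47 molecule",active,1,200.0
CD70,LYWQGGPALGR,P32970,"CD70 molecule",active,1,200.0
CD74,C[cam]QEEVSHIPAVHPGSFRPK,P04233,"CD74 molecule",active,1,200.0
CEACAM8,IIGYVISNQQITPGPAYSNR,P31997,"CEA cell adhesion molecule 8",active,1,200.0
CX3CL1,ALGTSPELPTGVTGSSGTR,P78423,"C-X3-C motif chemokine ligand 1",active,1,200.0
CXCL10,VEIIATMK,P02778,"C-X-C motif chemokine ligand 10",active,1,200.0
CXCL13,SIVC[cam]VDPQAEWIQR,O43927,"C-X-C motif chemokine ligand 13",active,1,200.0
ENTPD1,SLSNYPFDFQGAR,P49961,"ectonucleoside triphosphate diphosphohydrolase 1",active,1,200.0
FAS,EAY[ph]DTLIK,P25445,"Fas cell surface death receptor",active,1,200.0
FAS,EAYDTLIK,P25445,"Fas cell surface death receptor",active,1,200.0
GAPDH,GALQNIIPASTGAAK,P04406,"glyceraldehyde-3-phosphate dehydrogenase",active,10,200.0
HAVCR2,GAC[cam]PVFEC[cam]GNVVLR,Q8TDQ0,"hepatitis A virus cellular receptor 2",active,1,200.0
ICAM1,DGTFPLPIGESVTVTR,P05362,"intercellular adhesion molecule 1",active,1,200.0
ICOSLG,GLYDVVSVLR,O75144,"inducible T cell costimulator ligand",active,1,200.0
IL18,ISTLSC[cam]ENK,Q14116,"interleukin 18",active,1,200.0
ITGAE,VSYQLQTPEGQTDHPQPILDR,P38570,"integrin subunit alpha E",active,1,200.0
LGALS1,SFVLNLGK,P09382,"galectin 1",active,1,200.0
LIME1,SSTC[cam]GAGTPPASSC[cam]PSLGR,Q9H400,"Lck interacting transmembrane adaptor 1",failed_linearity,1,200.0
LIME1,SSTC[cam]GAGT[ph]PPASSC[cam]PSLGR,Q9H400,"Lck interacting transmembrane adaptor 1",failed_linearity,1,200.0
NFKB2,IEVDLVTHSDPPR,Q00653,"nuclear factor kappa B subunit 2",active,1,200.0
NT5E,VIYPAVEGR,P21589,"5’-nucleotidase ecto",active,1,200.0
PDCD1LG2,ATLLEEQLPLGK,Q9BQ51,"programmed cell death 1 ligand 2",active,1,200.0
PECAM1,DQNFVILEFPVEEQDR,P16284,"platelet and endothelial cell adhesion molecule 1",active,1,200.0
PSMA1,ETLPAEQDLTTK,P25786,"proteasome 20S subunit alpha 1",active,1,200.0
PTGS2,ALPPVPDDC[cam]PTPLGVK,P35354,"prostaglandin-endoperoxide synthase 2",active,1,200.0
PTPRC,DPPSEPSPLEAEFQR,P08575,"protein tyrosine phosphatase receptor type C",active,1,200.0
PTPRC,LFLAEFQSIPR,P08575,"protein tyrosine phosphatase receptor type C",active,1,200.0
RIF1,ASQGLLSSIENSESDSSEAK,Q5UIP0,"replication timing regulatory factor 1",active,1,200.0
STAT1,YTYEHDPITK,P42224,"signal transducer and activator of transcription 1",active,1,200.0
STAT3,TGVQFTTK,P40763,"signal transducer and activator of transcription 3",active,1,200.0
STAT6,GYVPATIK,P42226,"signal transducer and activator of transcription 6",active,1,200.0
TAP2,EAVGGLQTVR,Q03519,"transporter 2, ATP binding cassette subfamily B member",active,1,200.0
TNFRSF14,EDEYPVGSEC[cam]C[cam]PK,Q92956,"TNF receptor superfamily member 14",active,1,200.0
TNFRSF17,SLPAALS[ph]ATEIEK,Q02223,"TNF receptor superfamily member 17",active,1,200.0
TNFRSF17,SLPAALSATEIEK,Q02223,"TNF receptor superfamily member 17",active,1,200.0
TNFRSF9,NQIC[cam]SPC[cam]PPNSFSSAGGQR,Q07011,"TNF receptor superfamily member 9",active,10,200.0
TNFSF9,EGPELSPDDPAGLLDLR,P41273,"TNF superfamily member 9",active,1,200.0
VCAM1,TQIDSPLSGK,P19320,"vascular cell adhesion molecule 1",active,1,200.0
VSIR,GHDVTFYK,Q9H7M9,"V-set immunoregulatory receptor",failed_linearity,10,200.0
VTCN1,EGVLGLVHEFK,Q7Z7D3,"V-set domain containing T cell activation inhibitor 1",active,1,200.0
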