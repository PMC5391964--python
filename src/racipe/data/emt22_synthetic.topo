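# Synthetic reconstruction of a 22-node / 82-edge core EMT decision circuit:
# 13 transcription-factor-class nodes (including the CDH1 and VIM readouts)
# and 9 microRNAs.  The original curated edge list was not redistributable,
# so this fixture rebuilds the circuit from canonical EMT regulatory
# interactions under the documented structural constraints: miR-30c,
# miR-205 and miR-9 are pure inputs (no incoming regulation), microRNAs
# co-cluster with CDH1 against the TF/VIM block, and the decision backbone
# is a cascade of mutual-inhibition switches — miR-34a/SNAIL upstream of
# miR-200b,c/ZEB1 upstream of miR-200a,miR-141/ZEB2 — reflecting that
# SNAIL turns on before the ZEB factors along the E -> hybrid E/M -> M
# progression.  TGFB1, repressed by the miR-200 family and inducing SNAI1
# and the peripheral TFs, closes the canonical feedback from the ZEB
# switches back onto SNAIL.  microRNA translational repression is encoded
# as ordinary inhibition (type 2), like every other link.
# Type: 1 = activation, 2 = inhibition.
Source	Target	Type
# --- input microRNAs (no feedback; outgoing repression only) ------------
# miR-9 directly targets the CDH1 transcript.
miR-9	CDH1	2
# miR-30c targets SNAI1 and vimentin.
miR-30c	SNAI1	2
miR-30c	VIM	2
# miR-205 targets both ZEB factors.
miR-205	ZEB1	2
miR-205	ZEB2	2
# --- switch 1: SNAIL / miR-34a mutual inhibition ------------------------
SNAI1	miR-34a	2
SNAI2	miR-34a	2
miR-34a	SNAI1	2
miR-34a	SNAI2	2
# SNAI1 negative autoregulation.
SNAI1	SNAI1	2
# --- switch 2: ZEB1 / miR-200b,c mutual inhibition ----------------------
ZEB1	miR-200b	2
ZEB1	miR-200c	2
miR-200b	ZEB1	2
miR-200c	ZEB1	2
# --- switch 3: ZEB2 / miR-200a,miR-141 mutual inhibition ----------------
ZEB2	miR-200a	2
ZEB2	miR-141	2
miR-200a	ZEB2	2
miR-141	ZEB2	2
# --- switch 1 drives switch 2 (SNAIL upstream of ZEB1) ------------------
SNAI1	miR-200b	2
SNAI1	miR-200c	2
SNAI1	ZEB1	1
miR-34a	ZEB1	2
# --- switch 2 and switch 3 couple through the shared miR-200 family -----
ZEB1	miR-200a	2
ZEB1	miR-141	2
ZEB2	miR-200b	2
ZEB2	miR-200c	2
# --- miR-101 loop (keeps miR-101 under feedback, unlike the 3 inputs) ---
ZEB1	miR-101	2
SNAI1	miR-101	2
miR-101	ZEB1	2
miR-101	ZEB2	2
# --- transcriptional repression of the epithelial readout CDH1 ----------
SNAI1	CDH1	2
SNAI2	CDH1	2
ZEB1	CDH1	2
ZEB2	CDH1	2
TWIST1	CDH1	2
TWIST2	CDH1	2
GSC	CDH1	2
FOXC2	CDH1	2
KLF8	CDH1	2
TCF3	CDH1	2
# --- activation of the mesenchymal readout VIM --------------------------
SNAI1	VIM	1
SNAI2	VIM	1
ZEB1	VIM	1
ZEB2	VIM	1
TWIST1	VIM	1
TWIST2	VIM	1
GSC	VIM	1
FOXC2	VIM	1
KLF8	VIM	1
TCF3	VIM	1
TGFB1	VIM	1
CDH1	VIM	2
miR-101	VIM	2
# --- TF cascade within the mesenchymal block ----------------------------
SNAI1	SNAI2	1
TWIST1	SNAI2	1
TWIST1	TWIST2	1
TWIST1	GSC	1
SNAI1	GSC	1
SNAI2	GSC	1
TWIST2	GSC	1
KLF8	GSC	1
TWIST1	FOXC2	1
SNAI1	FOXC2	1
SNAI2	FOXC2	1
TWIST2	FOXC2	1
GSC	FOXC2	1
KLF8	FOXC2	1
GSC	TCF3	1
TWIST1	KLF8	1
TWIST2	KLF8	1
TWIST1	ZEB1	1
# --- TGFB1 signalling module with miR-200 feedback ----------------------
TGFB1	SNAI1	1
TGFB1	TWIST1	1
TGFB1	TWIST2	1
TGFB1	KLF8	1
TGFB1	TCF3	1
TGFB1	GSC	1
TGFB1	FOXC2	1
miR-200a	TGFB1	2
miR-200b	TGFB1	2
miR-200c	TGFB1	2
miR-141	TGFB1	2
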