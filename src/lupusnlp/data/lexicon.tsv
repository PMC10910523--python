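lupus nephritis	C0024143	Lupus nephritis
lupus glomerulonephritis	C0024143	Lupus nephritis
nephritis	C0027697	Nephritis
glomerulonephritis	C0027697	Nephritis (glomerular inflammation)
kidney	C0022646	Kidney
kidney disease	C0022658	Kidney disease
renal disease	C0022658	Kidney disease
renal disorder	C0022658	Kidney disease
proteinuria	C0033687	Proteinuria
protein in urine	C1962972	Proteinuria finding
proteinuria finding	C1962972	Proteinuria finding
kidney biopsy	C0194073	Kidney biopsy
renal biopsy	C0194073	Kidney biopsy
urine creatinine	C1318439	Urine creatinine measurement
urine creatinine level	C0428283	Urine creatinine level finding
urine protein	C0262923	Urine protein test
urine protein test	C0262923	Urine protein test
membranous lupus nephritis	C4054543	Membranous lupus nephritis
lupus membranous nephropathy	C4054543	Membranous lupus nephritis
lupus nephritis class ii	C4053958	Systemic lupus erythematosus nephritis class II
sle nephritis class ii	C4053958	Systemic lupus erythematosus nephritis class II
lupus nephritis class iii	C4053959	Systemic lupus erythematosus nephritis class III
sle nephritis class iii	C4053959	Systemic lupus erythematosus nephritis class III
lupus nephritis class iv	C4053955	Systemic lupus erythematosus nephritis class IV
sle nephritis class iv	C4053955	Systemic lupus erythematosus nephritis class IV
lupus nephritis class v	C0268758	Lupus glomerulonephritis syndrome, WHO class V
sle nephritis class v	C0268758	Lupus glomerulonephritis syndrome, WHO class V
diffuse lupus glomerulonephritis	C0268757	Lupus glomerulonephritis syndrome, WHO class IV
who class iv lupus glomerulonephritis	C0268757	Lupus glomerulonephritis syndrome, WHO class IV
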