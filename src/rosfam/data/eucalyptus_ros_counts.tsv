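organism	family	source	complete	partial	pseudogene
camaldulensis	1CysPrx	database	2	0	1
camaldulensis	1CysPrx	pcr	0	0	1
camaldulensis	2CysPrx	database	0	1	0
camaldulensis	2CysPrx	pcr	0	0	0
camaldulensis	APx	database	3	5	2
camaldulensis	APx	pcr	0	0	0
camaldulensis	APx-R	database	1	0	1
camaldulensis	APx-R	pcr	0	0	0
camaldulensis	CIII Prx	database	84	39	40
camaldulensis	CIII Prx	pcr	0	6	10
camaldulensis	DiOx	database	1	0	0
camaldulensis	DiOx	pcr	0	0	0
camaldulensis	GPx	database	3	5	3
camaldulensis	GPx	pcr	0	0	0
camaldulensis	Kat	database	1	4	7
camaldulensis	Kat	pcr	0	1	1
camaldulensis	PrxII	database	3	0	0
camaldulensis	PrxII	pcr	0	0	0
camaldulensis	PrxQ	database	1	0	0
camaldulensis	PrxQ	pcr	0	0	0
camaldulensis	Rboh	database	3	4	0
camaldulensis	Rboh	pcr	0	0	0
globulus	1CysPrx	database	0	2	2
globulus	1CysPrx	pcr	0	0	0
globulus	2CysPrx	database	1	0	0
globulus	2CysPrx	pcr	0	0	0
globulus	APx	database	7	0	3
globulus	APx	pcr	0	0	1
globulus	APx-R	database	1	0	0
globulus	APx-R	pcr	0	0	0
globulus	CIII Prx	database	93	32	55
globulus	CIII Prx	pcr	0	2	1
globulus	DiOx	database	1	0	0
globulus	DiOx	pcr	0	0	0
globulus	GPx	database	5	3	2
globulus	GPx	pcr	0	0	0
globulus	Kat	database	3	3	8
globulus	Kat	pcr	0	0	0
globulus	PrxII	database	2	1	0
globulus	PrxII	pcr	0	0	0
globulus	PrxQ	database	0	1	0
globulus	PrxQ	pcr	0	0	0
globulus	Rboh	database	5	2	0
globulus	Rboh	pcr	0	0	0
grandis	1CysPrx	database	1	0	2
grandis	1CysPrx	pcr	0	0	0
grandis	2CysPrx	database	1	0	0
grandis	2CysPrx	pcr	0	0	0
grandis	APx	database	7	0	4
grandis	APx	pcr	0	0	0
grandis	APx-R	database	1	0	1
grandis	APx-R	pcr	0	0	0
grandis	CIII Prx	database	126	2	51
grandis	CIII Prx	pcr	2	5	5
grandis	DiOx	database	1	0	0
grandis	DiOx	pcr	0	0	0
grandis	GPx	database	9	0	0
grandis	GPx	pcr	0	0	1
grandis	Kat	database	2	4	6
grandis	Kat	pcr	0	1	1
grandis	PrxII	database	3	0	0
grandis	PrxII	pcr	0	0	0
grandis	PrxQ	database	1	0	0
grandis	PrxQ	pcr	0	0	0
grandis	Rboh	database	7	0	0
grandis	Rboh	pcr	0	0	0
gunnii	1CysPrx	database	1	0	2
gunnii	1CysPrx	pcr	0	0	1
gunnii	2CysPrx	database	1	0	0
gunnii	2CysPrx	pcr	0	0	0
gunnii	APx	database	7	0	3
gunnii	APx	pcr	0	0	0
gunnii	APx-R	database	1	0	1
gunnii	APx-R	pcr	0	0	0
gunnii	CIII Prx	database	100	11	48
gunnii	CIII Prx	pcr	1	8	8
gunnii	DiOx	database	1	0	0
gunnii	DiOx	pcr	0	0	0
gunnii	GPx	database	7	1	1
gunnii	GPx	pcr	0	0	1
gunnii	Kat	database	4	2	7
gunnii	Kat	pcr	0	1	0
gunnii	PrxII	database	2	1	0
gunnii	PrxII	pcr	0	0	0
gunnii	PrxQ	database	1	0	0
gunnii	PrxQ	pcr	0	0	0
gunnii	Rboh	database	6	1	0
gunnii	Rboh	pcr	0	0	0
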