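3017382	France	France	Republique francaise	46.0	2.0	A	PCLI	FR		00				67000000		107	Europe/Paris	2024-01-01
3012874	Île-de-France	Ile-de-France	Region Parisienne	48.5	2.5	A	ADM1	FR		11				12278210		85	Europe/Paris	2024-01-01
2988507	Paris	Paris	Lutece,Paname	48.85341	2.3488	P	PPLC	FR		11	75			2138551		42	Europe/Paris	2024-01-01
2510769	Spain	Spain	Espana,Reino de Espana	40.0	-4.0	A	PCLI	ES		00				47000000		660	Europe/Madrid	2024-01-01
3117735	Madrid	Madrid	Villa de Madrid	40.4165	-3.70256	P	PPLC	ES		29	M			3255944		665	Europe/Madrid	2024-01-01
2519402	Ciudad Real	Ciudad Real		38.98626	-3.92907	P	PPLA2	ES		54	CR			74746		630	Europe/Madrid	2024-01-01
2264397	Portugal	Portugal	Republica Portuguesa	39.5	-8.0	A	PCLI	PT		00				10300000		255	Europe/Lisbon	2024-01-01
2267057	Lisbon	Lisbon	Lisboa	38.71667	-9.13333	P	PPLC	PT		14				517802		45	Europe/Lisbon	2024-01-01
8012658	Real	Real		41.3	-8.55	P	PPL	PT		18				9470		150	Europe/Lisbon	2024-01-01
3469034	Brazil	Brazil	Brasil	-10.0	-55.0	A	PCLI	BR		00				211000000		320	America/Sao_Paulo	2024-01-01
3448439	São Paulo	Sao Paulo	Sampa	-23.5475	-46.63611	P	PPLA	BR		27				12330000		769	America/Sao_Paulo	2024-01-01
2635167	United Kingdom	United Kingdom	Britain,Great Britain,UK	54.0	-2.0	A	PCLI	GB		00				67000000		100	Europe/London	2024-01-01
2643743	London	London	Londres	51.50853	-0.12574	P	PPLC	GB		ENG	GLA			8961989		25	Europe/London	2024-01-01
3865483	Argentina	Argentina	Republica Argentina	-34.0	-64.0	A	PCLI	AR		00				45000000		500	America/Buenos_Aires	2024-01-01
3435910	Buenos Aires	Buenos Aires	Baires	-34.61315	-58.37723	P	PPLC	AR		07				2891000		25	America/Buenos_Aires	2024-01-01
6252001	United States	United States	USA,America,United States of America	39.76	-98.5	A	PCLI	US		00				331000000		540	America/Chicago	2024-01-01
5128581	New York	New York	NYC,New York City	40.71427	-74.00597	P	PPL	US		NY				8804190		10	America/New_York	2024-01-01
2921044	Germany	Germany	Deutschland,Bundesrepublik Deutschland	51.0	9.0	A	PCLI	DE		00				83000000		303	Europe/Berlin	2024-01-01
2950159	Berlin	Berlin	Berlino	52.52437	13.41053	P	PPLC	DE		16	00			3426354		43	Europe/Berlin	2024-01-01
3489940	Kingston	Kingston		17.99702	-76.79358	P	PPLC	JM		01				937700		30	America/Jamaica	2024-01-01
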